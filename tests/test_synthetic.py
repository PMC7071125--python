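"""Scene generator tests: determinism, ground-truth consistency, and the
guarantee that scripted trajectories satisfy their behavior's rule system."""

import numpy as np
import pytest

from calfvision.detection import box_from_mask
from calfvision.features import extract_features, windowed_means
from calfvision.rules import ZoneConfig, RuleThresholds, classify_frames
from calfvision.synthetic import (
    Background,
    BehaviorSegment,
    CalfSprite,
    SceneScript,
    SpritePlacement,
    default_calf_sprite,
    frames_checksum,
    make_drinking_script,
    make_entering_script,
    make_feeding_script,
    make_leaving_script,
    make_still_script,
    make_turning_script,
    render_scene,
    script_from_dict,
    script_to_dict,
    true_boxes,
)


def simple_script(n=10, visible=True, noise=0.0, seed=0):
    placements = tuple(SpritePlacement(30, 20, visible=visible) for _ in range(n))
    return SceneScript(
        n_frames=n,
        segments=(BehaviorSegment("none", 1, n, placements),),
        sprite=default_calf_sprite(16, 24),
        background=Background(level=120, strip_width=8, strip_tone=60),
        frame_size=(80, 100),
        noise_sigma=noise,
        seed=seed,
    )


class TestRenderScene:
    def test_no_target_noiseless_constant_frames(self):
        script = simple_script(visible=False)
        script = SceneScript(
            n_frames=script.n_frames, segments=script.segments, sprite=script.sprite,
            background=Background(level=120, strip_width=0), frame_size=script.frame_size,
            noise_sigma=0.0, seed=0,
        )
        frames, truth = render_scene(script)
        assert (frames == 120).all()
        assert not truth.masks.any()
        assert all(b is None for b in truth.boxes)

    def test_static_sprite_frames_identical(self):
        frames, truth = render_scene(simple_script())
        assert all(np.array_equal(frames[0], f) for f in frames)
        assert len({(b.uend, b.dend, b.lend, b.rend) for b in truth.boxes}) == 1

    def test_deterministic_for_same_script_and_seed(self):
        a, _ = render_scene(simple_script(noise=4.0, seed=7))
        b, _ = render_scene(simple_script(noise=4.0, seed=7))
        assert frames_checksum(a) == frames_checksum(b)

    def test_different_seed_changes_noise(self):
        a, _ = render_scene(simple_script(noise=4.0, seed=7))
        b, _ = render_scene(simple_script(noise=4.0, seed=8))
        assert frames_checksum(a) != frames_checksum(b)

    def test_truth_box_equals_exhaustive_mask_scan(self):
        script = make_entering_script(noise_sigma=0)
        _, truth = render_scene(script)
        for mask, box in zip(truth.masks, truth.boxes):
            raw = box_from_mask(mask)
            if raw is None:
                assert box is None
            else:
                assert (box.uend, box.dend, box.lend, box.rend) == (
                    raw.utest, raw.dtest, raw.ltest, raw.rtest,
                )

    def test_sprite_clipped_at_frame_border(self):
        script = simple_script()
        placements = tuple(SpritePlacement(30, -10) for _ in range(5))
        clipped = SceneScript(
            n_frames=5, segments=(BehaviorSegment("none", 1, 5, placements),),
            sprite=script.sprite, background=script.background,
            frame_size=script.frame_size, noise_sigma=0.0, seed=0,
        )
        _, truth = render_scene(clipped)
        assert truth.boxes[0].lend == 1
        assert truth.boxes[0].width == 24 - 11  # 11 columns fall outside

    def test_entering_truth_br_bd_decrease_bl_pins(self):
        script = make_entering_script(noise_sigma=0)
        _, truth = render_scene(script)
        idx = [i for i, lab in enumerate(truth.labels) if lab == "enter"]
        br = np.array([truth.boxes[i].rend for i in idx], dtype=float)
        bl = np.array([truth.boxes[i].lend for i in idx], dtype=float)
        assert (np.diff(br) <= 0).all()
        assert (bl < 30).all()


class TestScriptBuilders:
    @pytest.mark.parametrize(
        "builder,label",
        [
            (make_entering_script, "enter"),
            (make_leaving_script, "leave"),
            (make_still_script, "still"),
            (make_turning_script, "turn"),
        ],
    )
    def test_scripts_self_consistent_with_rules(self, builder, label):
        """Classifying the TRUE boxes reproduces the scripted labels."""
        script = builder(noise_sigma=0)
        series = extract_features(true_boxes(script))
        predicted = classify_frames(series)
        scripted = script.labels()
        in_window = [i for i, lab in enumerate(scripted) if lab == label]
        assert len(in_window) >= 8
        agree = sum(predicted[i] == label for i in in_window)
        assert agree / len(in_window) >= 0.95

    def test_entering_rule_holds_directly_on_true_features(self):
        """Spot-check the entering inequality system itself on labeled frames."""
        thresholds = RuleThresholds()
        script = make_entering_script(noise_sigma=0)
        series = extract_features(true_boxes(script))
        labeled = [i + 1 for i, lab in enumerate(script.labels()) if lab == "enter"]
        for n in labeled:
            wf = windowed_means(series, n)
            assert wf.defined
            assert wf.prev_br - wf.next_br > thresholds.move_thresh
            assert wf.prev_bd - wf.next_bd > thresholds.move_thresh
            assert abs(wf.prev_bl - wf.next_bl) < thresholds.bl_change_bound
            assert series.bl[n - 6] < thresholds.bl_gate

    def test_too_slow_trajectory_rejected(self):
        with pytest.raises(ValueError, match="displacement"):
            make_entering_script(speed=2)  # 5*2 = 10 px does not exceed 10

    def test_feeding_script_guarantee(self):
        script, rois = make_feeding_script(head_size=(40, 50), bottom_row=48, noise_sigma=0)
        assert script.labels().count("feed") == 50

    def test_impossible_feeding_params_rejected(self):
        with pytest.raises(ValueError, match="feeding"):
            make_feeding_script(head_size=(30, 50), bottom_row=30)  # bottom above Df-5

    def test_impossible_drinking_params_rejected(self):
        with pytest.raises(ValueError, match="drinking"):
            make_drinking_script(head_size=(40, 40))  # 1600 px <= St


class TestScriptValidation:
    def test_segments_must_tile_frames(self):
        pl = (SpritePlacement(1, 1),)
        with pytest.raises(ValueError, match="tile|cover"):
            SceneScript(
                n_frames=3,
                segments=(BehaviorSegment("none", 1, 1, pl), BehaviorSegment("none", 3, 3, pl)),
                sprite=default_calf_sprite(8, 10),
                frame_size=(40, 50),
            )

    def test_trajectory_length_must_match_segment(self):
        with pytest.raises(ValueError, match="trajectory"):
            BehaviorSegment("none", 1, 5, (SpritePlacement(1, 1),) * 3)

    def test_sprite_pattern_shape_checked(self):
        with pytest.raises(ValueError, match="tone_pattern"):
            CalfSprite((10, 12), np.ones((5, 5), dtype=bool))

    def test_sprite_must_fit_in_frame(self):
        with pytest.raises(ValueError, match="smaller"):
            simple_script().__class__(
                n_frames=1,
                segments=(BehaviorSegment("none", 1, 1, (SpritePlacement(1, 1),)),),
                sprite=default_calf_sprite(120, 160),
                frame_size=(100, 100),
            )


class TestSerialization:
    def test_round_trip_preserves_script(self):
        script = make_turning_script(noise_sigma=2.5, seed=9)
        restored = script_from_dict(script_to_dict(script))
        assert restored.n_frames == script.n_frames
        assert restored.labels() == script.labels()
        a, _ = render_scene(script)
        b, _ = render_scene(restored)
        assert frames_checksum(a) == frames_checksum(b)
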