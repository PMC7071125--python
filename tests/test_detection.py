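"""Detection tests: box expansion, background synthesis, the integrated model
and its two baselines, each checked against simple independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calfvision.detection import (
    BackgroundState,
    DetectionParams,
    RawBox,
    TargetBox,
    box_from_mask,
    detect_sequence,
    expand_box,
    frame_difference_baseline,
    static_background_baseline,
    subtract_background,
    synthesize_background,
)
from calfvision.synthetic import make_still_script, render_scene


def eq1_oracle(u, d, l, r, height, width, margin=5):
    """Literal four-branch border expansion with image-border clamping."""
    ue = u - margin if u - margin >= 1 else 1
    de = d + margin if d + margin <= height else height
    le = l - margin if l - margin >= 1 else 1
    re_ = r + margin if r + margin <= width else width
    return ue, de, le, re_


def iou(a, b):
    union = np.logical_or(a, b).sum()
    return np.logical_and(a, b).sum() / union if union else 1.0


class TestExpandBox:
    def test_interior_box_expands_five(self):
        box = expand_box(RawBox(100, 200, 50, 300))
        assert (box.uend, box.dend, box.lend, box.rend) == (95, 205, 45, 305)

    def test_top_clamp(self):
        box = expand_box(RawBox(3, 200, 50, 300))
        assert box.uend == 1

    def test_bottom_and_right_clamp(self):
        box = expand_box(RawBox(100, 574, 50, 701))
        assert box.dend == 576 and box.rend == 704

    def test_rejects_box_outside_image(self):
        with pytest.raises(ValueError):
            expand_box(RawBox(1, 10, 1, 30), height=20, width=20)

    @settings(derandomize=True, max_examples=300)
    @given(data=st.data())
    def test_expansion_is_exact_or_pinned_at_border(self, data):
        """Each expanded border either moves by exactly the margin or sits on
        the image border, and the search box always contains the tight box."""
        height = data.draw(st.integers(10, 600), label="height")
        width = data.draw(st.integers(10, 720), label="width")
        u = data.draw(st.integers(1, height), label="u")
        d = data.draw(st.integers(u, height), label="d")
        l = data.draw(st.integers(1, width), label="l")
        r = data.draw(st.integers(l, width), label="r")
        margin = data.draw(st.integers(0, 12), label="margin")
        box = expand_box(RawBox(u, d, l, r), height, width, margin)
        assert 1 <= box.uend <= u and d <= box.dend <= height
        assert 1 <= box.lend <= l and r <= box.rend <= width
        assert box.uend == u - margin or box.uend == 1
        assert box.dend == d + margin or box.dend == height
        assert box.lend == l - margin or box.lend == 1
        assert box.rend == r + margin or box.rend == width

    def test_exhaustive_oracle_on_20x20_grid(self):
        for u in range(1, 21):
            for d in range(u, 21):
                for l in range(1, 21):
                    for r in range(l, 21):
                        box = expand_box(RawBox(u, d, l, r), height=20, width=20)
                        assert (box.uend, box.dend, box.lend, box.rend) == eq1_oracle(
                            u, d, l, r, 20, 20
                        )


class TestBoxFromMask:
    def test_empty_mask_gives_none(self):
        assert box_from_mask(np.zeros((5, 5), dtype=bool)) is None

    def test_tight_box(self):
        m = np.zeros((10, 12), dtype=bool)
        m[2:5, 3:9] = True
        raw = box_from_mask(m)
        assert (raw.utest, raw.dtest, raw.ltest, raw.rtest) == (3, 5, 4, 9)


class TestSynthesizeBackground:
    def test_full_frame_box_returns_previous_background(self, rng):
        bg = rng.integers(0, 256, (20, 30), dtype=np.uint8)
        frame = rng.integers(0, 256, (20, 30), dtype=np.uint8)
        state = BackgroundState(background=bg)
        out = synthesize_background(frame, TargetBox(1, 20, 1, 30), state)
        assert np.array_equal(out, bg)

    def test_single_pixel_box(self, rng):
        bg = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        frame = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        out = synthesize_background(frame, TargetBox(4, 4, 7, 7), BackgroundState(background=bg))
        assert out[3, 6] == bg[3, 6]
        mask = np.ones((10, 10), dtype=bool)
        mask[3, 6] = False
        assert np.array_equal(out[mask], frame[mask])

    def test_pixelwise_two_source_partition(self, rng):
        """Every output pixel comes from the prescribed source (oracle)."""
        for _ in range(100):
            h, w = 15, 18
            bg = rng.integers(0, 256, (h, w), dtype=np.uint8)
            frame = rng.integers(0, 256, (h, w), dtype=np.uint8)
            u = int(rng.integers(1, h + 1)); d = int(rng.integers(u, h + 1))
            l = int(rng.integers(1, w + 1)); r = int(rng.integers(l, w + 1))
            box = TargetBox(u, d, l, r)
            out = synthesize_background(frame, box, BackgroundState(background=bg))
            for i in range(h):
                for j in range(w):
                    inside = u <= i + 1 <= d and l <= j + 1 <= r
                    assert out[i, j] == (bg[i, j] if inside else frame[i, j])


class TestSubtractBackground:
    def make_block_scene(self, offset=0):
        bg = np.full((100, 120), 100 + offset, dtype=np.uint8)
        frame = bg.copy()
        frame[20:80, 40:70] = 200 + offset  # 60x30 block
        true = np.zeros_like(bg, dtype=bool)
        true[20:80, 40:70] = True
        return frame, bg, true

    def test_identical_frame_gives_empty_mask(self):
        bg = np.full((50, 60), 90, dtype=np.uint8)
        state = BackgroundState.from_frame(bg)
        assert not subtract_background(bg, state).any()

    def test_block_recovered_exactly(self):
        # The 3x3 median pre-filter shaves the four 1-px convex corners of
        # the block (a corner pixel has only 4 of 9 block neighbors), and
        # closing cannot refill a convex-corner notch; the rest is exact.
        frame, bg, true = self.make_block_scene()
        mask = subtract_background(frame, BackgroundState.from_frame(bg))
        expected = true.copy()
        for i, j in ((20, 40), (20, 69), (79, 40), (79, 69)):
            expected[i, j] = False
        assert np.array_equal(mask, expected)

    def test_invariant_to_common_constant_shift(self):
        frame, bg, _ = self.make_block_scene()
        frame2, bg2, _ = self.make_block_scene(offset=30)
        m1 = subtract_background(frame, BackgroundState.from_frame(bg))
        m2 = subtract_background(frame2, BackgroundState.from_frame(bg2))
        assert np.array_equal(m1, m2)

    def test_dimension_mismatch_rejected(self):
        state = BackgroundState(background=np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8), dtype=np.uint8), state)


class TestDetectSequence:
    def test_static_target_detected_every_frame(self):
        script = make_still_script(n_frames=30, noise_sigma=0.0)
        frames, truth = render_scene(script)
        bg = script.background.render(script.frame_size)
        results = detect_sequence(frames, bg)
        ious = [iou(m, t) for (_, m), t in zip(results, truth.masks)]
        assert all(b is not None for b, _ in results)
        assert np.mean(ious) >= 0.7

    def test_empty_scene_all_absent(self):
        bg = np.full((50, 60), 120, dtype=np.uint8)
        frames = np.stack([bg] * 5)
        results = detect_sequence(frames, bg)
        assert all(box is None for box, _ in results)

    def test_moving_target_tracks_ground_truth(self):
        params = DetectionParams()
        bg = np.full((80, 200), 120, dtype=np.uint8)
        frames, trues = [], []
        for k in range(20):
            f = bg.copy()
            c = 20 + 4 * k
            f[30:60, c : c + 40] = 220
            frames.append(f)
            trues.append((31, 60, c + 1, c + 40))
        results = detect_sequence(np.stack(frames), bg, params)
        slack = params.margin + params.closing_size
        for (box, _), (u, d, l, r) in zip(results, trues):
            assert box is not None
            assert abs(box.uend - u) <= slack and abs(box.dend - d) <= slack
            assert abs(box.lend - l) <= slack and abs(box.rend - r) <= slack

    def test_boxes_stay_inside_frame(self):
        script = make_still_script(n_frames=30, noise_sigma=5.0, col=-40)
        frames, _ = render_scene(script)
        bg = script.background.render(script.frame_size)
        for box, _ in detect_sequence(frames, bg):
            if box is not None:
                assert 1 <= box.uend <= box.dend <= 576
                assert 1 <= box.lend <= box.rend <= 704


class TestBaselines:
    def test_frame_difference_blind_to_static_target(self):
        frame = np.full((40, 50), 100, dtype=np.uint8)
        frame[10:30, 10:30] = 200
        masks = frame_difference_baseline(np.stack([frame] * 4))
        assert all(not m.any() for m in masks)

    def test_frame_difference_covers_symmetric_difference(self):
        bg = np.full((60, 120), 100, dtype=np.uint8)
        f1, f2 = bg.copy(), bg.copy()
        f1[20:40, 20:50] = 220
        f2[20:40, 50:80] = 220  # step move by a full block width
        masks = frame_difference_baseline([f1, f2], DetectionParams(min_area=10))
        sym = np.zeros_like(bg, dtype=bool)
        sym[20:40, 20:80] = True  # old block xor new block (disjoint -> union)
        assert iou(masks[1], sym) > 0.9

    def test_static_background_sees_static_target(self):
        bg = np.full((40, 50), 100, dtype=np.uint8)
        frame = bg.copy()
        frame[5:35, 10:40] = 220
        masks = static_background_baseline(np.stack([frame] * 3), bg)
        true = np.zeros_like(bg, dtype=bool)
        true[5:35, 10:40] = True
        for i, j in ((5, 10), (5, 39), (34, 10), (34, 39)):
            true[i, j] = False  # convex corners shaved by the median pre-filter
        for m in masks:
            assert np.array_equal(m, true)

    def test_static_background_drift_produces_spurious_foreground(self):
        bg = np.full((40, 50), 100, dtype=np.uint8)
        drifted = np.clip(bg.astype(int) + 40, 0, 255).astype(np.uint8)
        masks = static_background_baseline(np.stack([drifted]), bg)
        assert masks[0].all()

    def test_frame_difference_needs_two_frames(self):
        with pytest.raises(ValueError):
            frame_difference_baseline([np.zeros((5, 5), dtype=np.uint8)])
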