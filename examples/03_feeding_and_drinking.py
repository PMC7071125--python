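"""Front-view basin analysis: feeding and drinking by area thresholds.

Renders two front-view scenes — a head dipping to the feeding-basin bottom,
and a drinking bout preceded by a smaller 'looking around' pose — and runs
the ROI head segmentation with the feeding rule (bottom border and area) and
the drinking rule (area only).
"""

from calfvision import PipelineConfig, analyze_front_video, render_scene
from calfvision import make_drinking_script, make_feeding_script
from calfvision.rules import recognition_table

config = PipelineConfig()

for name, builder in (("feeding", make_feeding_script), ("drinking", make_drinking_script)):
    script, rois = builder(noise_sigma=5.0, seed=3)
    frames, truth = render_scene(script)
    table = analyze_front_video(frames, rois, config.feed_drink,
                                detection_params=config.detection)
    counts = table["label"].value_counts().to_dict()
    rec = recognition_table(table["label"].tolist(), truth.labels, classes=("feed", "drink"))
    print(f"{name} scene — per-frame labels: {counts}")
    print(rec.round(2))
    print()

print("Feeding fires when the segmented head reaches the basin's bottom border")
print("(Dt >= Df - 5 with Df = 48) with area S >= 1950 px; drinking needs")
print("S > 2900 px, which the foreshortened 'looking' pose never reaches.")
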