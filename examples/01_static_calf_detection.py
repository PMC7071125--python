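"""Detect a motionless calf — the case where plain frame differencing fails.

Renders a noiseless synthetic pen scene with a stationary calf, runs the
integrated background model and the inter-frame difference baseline, and
compares their masks against the exact ground truth.
"""

import numpy as np

from calfvision import detect_sequence, frame_difference_baseline, make_still_script, render_scene


def mask_iou(a, b):
    union = np.logical_or(a, b).sum()
    return np.logical_and(a, b).sum() / union if union else 1.0


script = make_still_script(n_frames=50, noise_sigma=0.0)
frames, truth = render_scene(script)
background = script.background.render(script.frame_size)

integrated = detect_sequence(frames, background)
integrated_iou = np.mean([mask_iou(m, t) for (_, m), t in zip(integrated, truth.masks)])

differenced = frame_difference_baseline(frames)
differenced_iou = np.mean([mask_iou(m, t) for m, t in zip(differenced[1:], truth.masks[1:])])

print(f"integrated background model  mean IoU vs truth: {integrated_iou:.4f}")
print(f"inter-frame difference       mean IoU vs truth: {differenced_iou:.4f}")
print()
print("The integrated model re-synthesizes its background every frame and keeps")
print("segmenting the stationary animal almost perfectly; consecutive identical")
print("frames give the differencing baseline nothing to see, so its IoU is ~0.")
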