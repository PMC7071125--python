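# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of calfvision. It states how things are computed; every
number quoted as a result is produced by the test suite or by
`scripts/acceptance.py`.

## Detection model

The detector assumes one animal in front of an otherwise static scene.
Each frame is converted to grayscale (BT.601 weights, the analog-video and
MATLAB convention) and median-filtered (3×3 by default; the window is a
configuration value — 3×3 removes sensor salt noise with minimal boundary
erosion). The foreground is the Otsu segmentation of the absolute
difference between the filtered frame and the current synthetic background,
post-processed by small-area removal (default 100 px, far below any
plausible calf area at 704×576), morphological closing with a 4×4 square,
and hole filling.

The background update is the heart of the model: after expanding the tight
foreground box by a 5 px margin (clamped to the image border), the next
background copies the previous background inside the box and the current
frame outside it. Outside the target the background therefore tracks the
scene with zero lag, while inside it the stored pen appearance is preserved
indefinitely — which is why a motionless animal keeps being detected. When
no foreground survives post-processing, the entire current frame becomes the
new background (fastest possible re-adaptation). The first frame serves as
the initial background unless a target-free reference is supplied; for
synthetic scenes the pipeline uses the script's clean background plate.

Numerical conventions that matter for reproducibility:

* **Box coordinates** are 1-based inclusive (row 1 = top image row), so the
  border clamps read literally as `max(·, 1)` / `min(·, H or W)`; numpy
  slicing is derived from them in one place (`TargetBox.slices`).
* **Otsu's threshold** splits `{≤ t}` vs `{> t}` and breaks ties toward the
  smallest maximizing `t`. A single-level histogram is flagged degenerate.
* **Degeneracy guard.** A difference image that is "essentially flat" must
  not produce a spurious target. The guard is a minimum separation of 10
  gray levels between the two Otsu class means of the |difference| image
  (configurable, `DetectionParams.min_contrast`). A guard on the threshold
  *level* would misfire: a legitimate noiseless two-level difference image
  ties across the whole gap and the tie-break returns t = 0. Degenerate
  (constant) difference images map to all-foreground when the constant
  exceeds the guard — a stale background under a global illumination jump is
  reported as change, which is the honest answer a never-updated background
  deserves — and to empty otherwise.
* **Closing with an even element** needs an origin convention: the origin is
  the top-left pixel of the central 2×2 block. Outside the image counts as
  background for the dilation and foreground for the erosion, so closing is
  extensive (never removes mask pixels) up to the image border.
* **Connectivity**: 8-connectivity for foreground components, 4-connectivity
  for hole backgrounds — the standard pairing that avoids the checkerboard
  paradox. Component-size ties are broken by first pixel in row-major order.
* The 3×3 median pre-filter shaves the four 1-px convex corners of a
  perfectly rectangular target (4 of 9 window pixels belong to the block at
  a corner), and closing cannot refill a convex notch; segmented areas of
  sharp rectangles are therefore smaller by exactly 4 px. Real (and
  synthetic-noisy) silhouettes have no such ideal corners.
* Small-area removal is applied to the post-Otsu binary mask, before
  closing. Applying it before thresholding is not meaningful (the difference
  image is not binary), so the chain is: threshold → remove small areas →
  close → fill holes.

## Boundary features and windows

Per present frame the box yields `BR` (right border column), `BL` (left
border column) and `BD = BR − BL`. Displacement around frame `n` is measured
by two 10-frame means offset by half a window: the previous window covers
frames `[n−5, n+4]`, the next `[n, n+9]` (requiring `n ≥ 6` and both windows
inside the series). The published sum notation for these windows (11 index
values divided by 10) is internally inconsistent; the two-10-frame-window
reading preserves both the stated "average of 10 consecutive frames" and the
half-window lead/lag structure, and is the default. An 11-frame variant is
available via the `window` argument for sensitivity checks (the test suite
exercises it on constant series).

For a border moving linearly at `v` px/frame the two means differ by exactly
`5·v` px, which is the design rule for scripting scenes: the movement
threshold of 10 px demands `5·v > 10`, i.e. sustained motion faster than
2 px/frame.

Windows containing an absent frame are skipped (the frame is left
undetermined) rather than interpolated — interpolation would invent
positions the detector never produced.

## Behavior rules

The rule systems compare `prev − next` window means against two pixel
thresholds: movement 10 px, stillness 3 px. Enter/leave additionally bound
the left-border change by 30 px and gate on `BL(n−5) < 30` px: the calf
counts as interacting with the resting area only when its (possibly
partially occluded) left border hugs the dark strip. The two turning systems
combine a steady `BR` with opposite-signed `BD`/`BL` motion; one printed
turning branch has an unbalanced absolute-value bar on its `BL` term, read
here as `|prev − next| > 3`, the only reading that type-checks and mirrors
its sibling branch.

Precedence when several systems hold simultaneously is enter → leave →
still → turn, first match wins. Displacement-based labels are the stronger
evidence, and the choice makes the classifier a total deterministic
function. Two of the four turning sub-branches are logically subsumed by
enter/leave under this precedence (their conditions are strict subsets);
the reachable turning signatures are the two with a steady right border.

Frame eligibility gates on the *raw* `BR` of frame `n` lying in Area A (not
a windowed mean). Area A defaults to columns [1, 190] — 30 px of strip plus
one 160 px body length, matching its definition as "one body length" wide;
both zones are configuration values.

The recognition table is frame-based: for each true behavior class, the
percentage of its frames per predicted label, with undetermined predictions
collected in a `missed` column; rows sum to 100 %.

## Feeding and drinking

The front-view ROIs are fixed crops (feeding 91×91, drinking 251×192 px;
origins are configuration values since only the sizes are dictated by the
basin geometry). Head segmentation runs the same primitive chain as the
side view but keeps only the largest component (reflections and shadows in
the basin water produce secondary blobs). The feeding rule is a conjunction
of a bottom-border condition `Dt ≥ Df − 5` (`Df = 48`, ROI-local rows, with
5 px of slack for boundary jitter) and an area floor `S ≥ 1950` px
(inclusive); the drinking rule is `S > 2900` px (strict). `S` is a pixel
count — the thresholds only make sense as counts. Each ROI maintains its
own background, refreshed to the current crop whenever no head is detected;
the first frame initializes it and is assumed head-free. If both rules fire
on one frame (only possible through segmentation spill, as the ROIs are
disjoint) the frame counts as feeding and the conflict is flagged.

`Df` is interpreted in ROI-local coordinates: the basin bottom border is a
property of the crop, not of the full frame.

## Synthetic scenes

The generator renders what the detector assumes and nothing more: a flat
background (default gray 120) with a dark vertical strip at the left
(default 40 px wide, gray 60) standing in for the resting area; one
rectangular two-tone sprite (default 120×160 px, light base 200 with
interior dark patches at 20 — the black-and-white coat); i.i.d. additive
Gaussian pixel noise clipped to [0, 255] (default σ = 5, moderate sensor
noise). Identical script + seed reproduce bit-identical frames (checked by
checksum). Ground truth is exact: the mask is the sprite's clipped
footprint, the box its tight bounding box, and labels are per frame (the
evaluation metric is frame-based).

Sprite motion is rigid translation plus two optional per-frame transforms: a
horizontal mirror and a horizontal width scale (foreshortening). The width
scale is load-bearing: a rigid, fully visible sprite has constant `BD`, and
a left-clipped one produces the enter/leave signature, so no rigid
trajectory can reach the turning branches; foreshortening with a pinned
right border is exactly the side-view geometry of a pivoting animal. The
dark patches are kept interior to the body outline so that over the dark
strip only interior pixels can fall below the segmentation threshold — they
become holes, which hole filling recovers; the strip-tone/dark-tone gap is
configurable to reproduce the target-loss failure mode on demand.

The `make_*_script` builders construct trajectories that *provably* satisfy
their rule system on the noiseless true boxes (e.g. entering moves at
3 px/frame, giving windowed displacements of 15 px against the 10 px
threshold) and label exactly the frames on which the classifier, run on the
true boxes, emits the target label; lead-ins and transitions keep their
honest label (`still`) or `none`. Parameters that cannot satisfy the system
(too-slow walks, too-small heads) are rejected with an explanation. The
turning script yields relatively few labeled frames (~13 of 74) because the
`BL < 30` gate is only satisfied near the fully-extended pose — a property
of the rule system itself, not of the renderer.

Scripted speeds and sizes are chosen to satisfy the rule thresholds
comfortably (5·v = 15 px vs 10, areas 2200/3600 px vs 1950/2900); no pixel
calibration of real calf speed is implied. What the synthetic scenes do
*not* model: articulated gait, perspective, shadows, lighting drift,
photometric texture, multiple animals. Passing on them demonstrates the
correctness of the pipeline's logic and its noise robustness at σ ≤ 5, not
field accuracy on farm video.

## Sizes and runtimes

Default study scenes are full PAL frames (576×704) of 71–100 frames per
behavior; the static-target contrast uses 50 noiseless frames. The whole
test suite runs in about 70 s and the acceptance script in about one minute
on a single CPU.

## I/O

Sequences are exchanged as directories of numbered 8-bit PNGs (masks as
0/255 PNGs), scene scripts and pipeline configurations as YAML, results as
CSV plus a plain-text report containing no timestamps — reports are
byte-identical across reruns with the same input, configuration and seed.
Video containers are accepted only when an ffmpeg-backed imageio plugin is
present; otherwise a clear error points to PNG sequences.

## Known limitations

* Single-animal assumption is global; two similar-size blobs resolve to the
  larger one.
* The side/front gating assumes frame-index alignment between the two views.
* Behavior labels need 15 future frames (the next window), so the chain is
  intrinsically ~0.6 s non-causal at 25 fps.
* The enter/leave/turn gate (`BL < 30`) ties the rules to a resting area at
  the left image edge; other pen layouts require re-deriving the rule signs.
* Feeding cannot be distinguished from a head resting motionless in the
  basin (pre/post-feeding pauses), and drinking from basin-edge licking —
  failure modes of the area-threshold approach itself.
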