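# Methods

## Scene model and assumptions

The tracker assumes the recording geometry of a standard multi-well fly
plate: a fixed camera above flat transparent chambers on a bright, constant
backlight; one adult fly per circular arena; the fly body at least 4 px in
the image (anything smaller is indistinguishable from noise). Resolutions
from 640×480 upward work; the reference configuration is 1280×720 at
30 fps with up to 72 arenas of 16 mm diameter. Illumination drift, camera
motion, multiple flies per arena, and larval stages are out of scope.

## Coordinate and unit conventions

Pixel coordinates are 0-based with origin at the top-left corner, x
rightward, y downward; centroids are fractional. Angles are degrees from
the +x axis toward +y (clockwise on screen); body-axis angles live in
[0, 180), headings (tail→head) in [0, 360). Time converts to frames as
`frame = floor(t · fps)` and every bin is an integer frame count, so
repeated conversions cannot drift. Distances are pixels; when `mm_per_px`
is set (derivable from the 16 mm arena diameter), millimetre columns are
added next to — never instead of — the pixel columns.

## Background: per-pixel temporal mode

Up to `n_bg_frames` (default 800) frames are sampled uniformly **without
replacement** under `seed` (default 0); shorter videos use every frame.
The background is the per-pixel most frequent intensity over the sample,
ties broken to the **smallest** intensity. The tie rule is deterministic
and biases static dark impurities into the background, where the
difference threshold then cancels them. A fixed default seed makes runs
reproducible; pass a different seed to re-randomize. The mode is exact
whenever each fly occupies a given pixel in under half of the sampled
frames — with one walking fly per ~40 px arena this holds by a wide
margin. The known failure mode is a fly that never moves for the whole
video: it becomes part of the background and is never detected (its arena
reports 0% valid frames rather than a wrong position).

## Segmentation, blobs, orientation

A pixel is foreground iff `frame < fg_max_value` (default 120) and
`background − frame > bg_min_diff` (default 70). The difference is
**signed**: the scene is bright with dark flies, and an absolute
difference would admit bright glints. Foreground pixels are labelled with
8-connectivity (diagonally-touching fly pixels stay one body); components
under `min_area` (default 4 px) are discarded. The centroid is the
unweighted mean of member pixel coordinates — on a binary mask this equals
any intensity-weighted barycenter.

The body axis is the orientation of the longer side of the minimum-area
enclosing rectangle of the component, computed by rotating calipers over
the convex hull of the pixel centers; squares and other ties resolve to
the first hull edge in traversal order, which is deterministic under input
permutation. On rasterized elliptical bodies the minimum-area rectangle is
genuinely tilted at some orientations — pixelation clips the corners, so
the tightest rectangle can rotate off-axis by up to ~10° on a 13×5 px
body (mean error across orientations stays below 5°). This is a property
of the estimator, not of the implementation; the polarity step and all
downstream statistics tolerate it.

Head/tail polarity: of the two candidates `axis` and `axis + 180°`, the
one within 90° of the frame-to-frame velocity direction wins, provided
speed ≥ `speed_min` (default 1.0 px/frame — below that, direction is
noise-dominated and the previous polarity is carried). Head-versus-abdomen
wobble is deliberately ignored; at these resolutions it is not resolvable.

## Arenas and trajectory assembly

Layouts are either configured (explicit circle centers + radius, or a
regular rows×cols grid) or auto-detected from the background image with a
circular Hough transform, returned row-major. Circles must be pairwise
disjoint and fully inside the frame. Each blob is assigned to the arena
containing its centroid; per arena the largest blob wins (ties: topmost,
then leftmost), so a reflection or speck never displaces the fly.

Missing detections are **carried forward**, not interpolated: a vanished
dark fly on a bright field almost always means stillness or occlusion at
the rim, so carrying biases gaps toward "inactive", consistent with the
sleep definition. Gap frames are flagged `valid=false` so the invalid
fraction is always reportable; a leading gap backfills from the first
detection. There is no cross-arena identity logic — arenas are hard
partitions.

## Behavioral statistics

* **Distance** per `dist_bin` (default 600 s): sum of frame-to-frame
  displacements of carried positions; invalid frames contribute zero.
  Trailing partial bins are dropped, not rescaled, so bins are comparable
  across flies. Frame 0 has no predecessor, so a bin's sum is over the
  displacements *into* its frames.
* **Sleep**: maximal runs of frames whose displacement is below
  `eps_still` (default 1.0 px/frame), kept only if strictly longer than
  `sleep_min_duration` (default 300 s) — exactly five minutes of
  immobility is not sleep. `eps_still` exists because "complete
  inactivity" is unattainable under sub-pixel centroid jitter; 1 px on a
  ~3 mm fly is conservatively still. Per `sleep_bin` (default 1800 s) and
  group, the mean asleep-seconds per fly and the fraction of flies with
  ≥1 asleep frame are reported.
* **Angle change**: sampled once per second (stride `round(fps)`), the
  absolute circular difference (degrees, [0, 180]) of consecutive
  **movement-direction** angles by default. Body-orientation mode is
  available (`angle_mode: body`), but path direction is the default
  because tail/head polarity errors would otherwise dominate the
  statistic. Seconds with sampled displacement below `eps_still` px or
  undefined angles are excluded; an always-still fly reports a missing
  value, never 0°/s.
* **Heatmaps**: per arena, counts of rounded centroid positions over the
  arena's bounding box; `heatmap_remove_sleep` drops exactly the frames
  inside detected bouts. Group heatmaps sum member grids aligned by arena
  center — translation only, since chambers are rotationally symmetric.
  Normalized copies scale the maximum to 1.
* **Regional preference**: occupancy fractions over `region_bins`
  (default 3) equal-width bins of normalized radial distance; fractions
  sum to 1.
* **Group comparison**: Kruskal–Wallis on per-fly summaries (mean distance
  per bin by default), omnibus plus each treatment vs the control group
  (default: first label in table order). Pairwise p-values are reported
  unadjusted, with a clearly labelled Bonferroni column alongside. The
  all-values-identical degenerate case is reported as H = 0, p = 1.

## Synthetic data: what it emulates and what it does not

The simulator reproduces the features the tracker depends on: a flat
bright field (default intensity 230) with optional arena rims and static
sub-`min_area` dark specks; one dark ellipse per arena (default 3×1.5 px
semi-axes, intensity 40 — comfortably passing both default thresholds);
bounded persistent random walk (per-frame heading perturbation
`N(0, turn_sd)`, step `max(0, N(speed_mean, speed_sd))` with
`speed_sd = speed_mean/3` by default, specular reflection at the wall);
plantable frozen intervals for sleep; iid Gaussian pixel noise clipped to
[0, 255]. Defaults (2 px/frame mean speed, 0.15 rad/frame turns) give
walking-fly kinematics at the reference scale.

It does **not** emulate wings, legs, grooming micro-movements, shadows,
reflections off chamber walls, illumination texture, or compression
artifacts. Passing tests therefore demonstrate the correctness of the
algorithms under the stated scene assumptions, not robustness to every
artifact of real footage; the configurable thresholds exist precisely
because real scenes vary.

Fixtures are written as lossless PNG frame folders (bit-exact round trip);
container formats are supported for input when a decoder plugin is
present, but all tests use lossless backends so oracles are exact.

## Benchmark problem sizes

The packaged benchmarks use scaled-down scenes chosen to exercise every
code path with exact ground truth: tracking accuracy on 12 arenas ×
9,000 frames (five minutes at 30 fps, the defaults above); sleep recovery
on one arena at 5 fps for 36 minutes with planted 7-, 4- and 20-minute
immobile intervals (the 4-minute interval must be rejected by the strict
rule); the distance closed form on 18,030 frames of exact 2 px/frame
motion (one full 10-minute bin ≈ 36,000 px); statistical calibration on
2,000 replicates of 3 groups × 24 flies. Determinism: every random choice
(sampling, simulation, noise) flows from explicit seeds.

## Known limitations

* A fly immobile for the entire recording is absorbed into the background
  and reported as never-detected rather than asleep.
* Orientation is unreliable below ~2 px/frame and during long immobility
  (polarity is carried, not re-estimated).
* Auto arena detection needs visible rims and a radius hint for best
  results; configured layouts are canonical.
* Heading accuracy degrades for near-circular bodies (axis ill-defined);
  the minimum-area-rectangle tilt discussed above bounds axis accuracy at
  roughly ±10° worst case on small bodies.
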