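# flyarena

Video tracking and behavior analysis for single adult *Drosophila* housed one
per circular arena, filmed from above by a fixed camera over a bright
backlight. The package is aimed at labs running multi-well locomotor/sleep
assays (e.g. drug-response screens with dozens of flies in parallel on one
plate): it turns a recording plus a treatment-assignment table into per-fly
trajectories, locomotor and sleep statistics, occupancy heatmaps, and
rank-based group comparisons.

## Method

Tracking proceeds in four stages per video:

1. **Background modeling.** The static scene is estimated as the per-pixel
   *temporal mode* over up to 800 randomly sampled frames: for each pixel,
   the most frequent intensity across the sample (ties to the smaller
   value). Because each fly covers any pixel only transiently, the mode is
   the fly-free background.
2. **Foreground segmentation.** Pixel *p* of frame *F* is fly iff
   `F(p) < 120` **and** `B(p) − F(p) > 70` where *B* is the background:
   flies are dark, and the signed difference rejects static dark impurities
   that the mode folded into *B*. Both thresholds are configurable.
3. **Coordinates.** Foreground pixels are grouped into 8-connected
   components; components under 4 px are noise. The fly position is the
   barycenter (unweighted centroid) of the largest component whose centroid
   lies inside the arena circle.
4. **Orientation.** The body axis is the long side of the minimum-area
   enclosing rectangle of the component; head/tail polarity is resolved by
   the motion direction (the candidate within 90° of the velocity wins;
   below 1 px/frame the previous polarity is carried).

From the trajectory matrix (x, y, heading, valid per arena per frame) the
analysis layer computes: distance per time bin (default 10 min), sleep
bouts (immobility strictly longer than 5 min), per-group sleep status per
30-min bin, mean absolute angle change per second, per-fly and per-group
occupancy heatmaps (optionally with sleep removed), and radial
center-to-rim preference. Groups are compared with the Kruskal–Wallis
H-test (significance at p < 0.05), omnibus plus each treatment vs control.

A built-in simulator (`flyarena.synthfly`) renders multi-arena videos with
exact ground truth — bounded persistent random walks, plantable immobile
intervals, pixel noise, impurity specks — so every stage is testable
without real footage.

## Worked example

```python
import numpy as np
import flyarena as fa

# simulate 6 arenas (2 x 3), 60 s at 30 fps, mild sensor noise
params = fa.SynthParams(rows=2, cols=3, duration=1800, fps=30.0,
                        speed_mean=2.0, noise_sd=2.0, seed=1)
truth, stream, layout = fa.simulate(params)

bg = fa.estimate_background(stream, n=800, seed=0)
cfg = fa.RunConfig(
    arena=fa.config_io.ArenaConfig(mode="manual",
                                   centers=[tuple(c) for c in layout.centers],
                                   radius=float(layout.radii[0])),
    dist_bin=10.0, sleep_bin=20.0, sleep_min_duration=5.0,
)
traj = fa.track(stream, bg, layout, cfg)
err = np.hypot(traj.x - truth.x, traj.y - truth.y)
print(f"valid frames: {traj.valid.mean():.1%}   median error: {np.median(err):.2f} px")

dist = fa.behavior.bin_distances(traj, cfg.dist_bin)
per_fly = dist.groupby("arena")["distance_px"].mean()
print("mean distance per 10 s bin (px):", np.round(per_fly.to_numpy(), 1))

h, p = fa.kruskal_wallis(per_fly[:3], per_fly[3:])
print(f"Kruskal-Wallis H = {h:.3f}, p = {p:.3f}")
```

prints

```
valid frames: 100.0%   median error: 0.14 px
mean distance per 10 s bin (px): [600.7 597.7 593.3 594.1 597.6 598.9]
Kruskal-Wallis H = 0.048, p = 0.827
```

Every fly is found in every frame with sub-pixel accuracy; the six flies
walk at the simulated 2 px/frame (≈ 600 px per 10 s bin); and an arbitrary
3-vs-3 split of identically-simulated flies is, as it should be, not
significant.

The same pipeline runs from the shell:

```
flyarena-track simulate fixture/ --rows 2 --cols 3 --frames 1800 --fps 30
flyarena-track track fixture/config.yaml
flyarena-track analyze fixture/config.yaml
```

`analyze` writes the plot families (locomotor activity, sleep status,
per-fly and grouped heatmaps, angle change, regional preference), one CSV
per statistic, the trajectory arrays (`.npy` + CSV mirror), a config echo,
and a `manifest.csv` listing every output.

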