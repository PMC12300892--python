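# fishtrack3d

Image-based 3D tracking and stress-behavior analysis for a single fish in
a glass tank, with a ground-truthed synthetic data generator for
validation.

## The problem

Elevated ammonia is one of the most common welfare hazards in
aquaculture.  Its behavioral signature in fish is distinctive: the animal
restricts itself to a small region of the tank (often near the surface)
while moving *more*, not less — short, erratic, repetitive excursions
inside a shrinking volume.  A non-invasive way to quantify this is to
photograph the tank once per second from two orthogonal views (front and
top), recover the fish's 3D position from each simultaneous image pair,
and compare movement statistics between exposure groups.

`fishtrack3d` implements that entire measurement chain for a single fish:

1. **Detection** (`fishtrack3d.detect`) — consecutive frames of one view
   are cropped to the tank region, grayscaled and differenced; the
   absolute difference is thresholded at 60 gray levels; connected
   foreground regions are labeled and the largest region (if it covers at
   least `min_area_px` pixels) is taken as the fish.  Centroid, area and
   orientation come from the region's image moments.
2. **Fusion** (`fishtrack3d.fuse3d`) — per-view pixel coordinates are
   scaled to millimetres from the tank dimensions (front view: x/y, top
   view: x/z).  The two views' independent x estimates act as a
   consistency check: a pair is fused only when they agree within
   `x_tolerance_mm` (default 30 mm), and x is their mean.
3. **Kinematics** (`fishtrack3d.kinematics`) — step distances use the 3D
   Euclidean formula `d = sqrt((x2-x1)^2 + (y2-y1)^2 + (z2-z1)^2)`; at
   1 fps the per-step distance is the per-second speed.  Speeds are
   averaged in nonoverlapping 10-s windows (a 10-h recording yields
   exactly 3600 values), and space use is summarized as the visited
   fraction of a 10x10x10 occupancy grid.
4. **Statistics** (`fishtrack3d.behav_stats`) — per group, a one-sample
   Kolmogorov-Smirnov normality screen; across groups, the tie-corrected
   Kruskal-Wallis H test; and, only when H is significant, Dunn's post
   hoc test with Bonferroni correction to locate the differing pairs.
5. **Synthetic data** (`fishtrack3d.synthgen`) — an attractor-biased
   correlated random walk with a single `stress` knob in [0, 1] that
   simultaneously confines the fish toward a surface attractor and raises
   its target speed, rendered onto noisy dual-view frames (flicker,
   pixel noise, transient bubble artifacts) with the true trajectory
   retained, so detection accuracy and distance recovery can be scored
   without manual annotation.

## Worked example

Run the bundled four-group demo (10-minute recordings, one control plus
three stress levels):

```bash
fishtrack3d run-all --config configs/demo.yaml --out demo_out
```

This simulates, renders and analyzes roughly 4800 frames in about a
minute and writes detection/track/speed CSVs, figures and a provenance
JSON.  `demo_out/speed_summary.csv` then contains (abridged):

```
group_label  n   mean   sd     min    max
control      60  18.91  1.13   15.48  21.85
low          60  21.16  1.55   17.02  24.25
mid          60  23.42  1.20   20.44  25.70
high         60  34.49  1.87   29.73  37.99
```

i.e. mean 10-s speeds in mm/s per group.  The provenance counts show the
confinement-activity trade-off directly: total distance grows from
11.3 m (control) to 20.7 m (high) while the visited fraction of the
occupancy grid falls from 0.21 to 0.05.  The Kruskal-Wallis test gives
H = 203.7 (df = 3, p = 6.7e-44), and `demo_out/dunn_matrix.csv` holds the
Bonferroni-adjusted Dunn matrix — in this demo every pair separates, the
high group most sharply (adjusted p = 9.8e-42 against control).
`trajectory_<group>.png` shows the green-to-red time-gradient 3D scatter
per group; the control cloud fills the tank while the high-stress cloud
collapses to a band under the water surface.

Detection accuracy against the rendered ground truth is reported per
group in `provenance.json` (0.99-1.00 here, at a 5 px tolerance).

The same stages are available as composable commands
(`simulate`, `detect`, `fuse`, `analyze`, `validate`, `plot`) operating
on PNG datasets and CSV logs, and as plain library calls:

```python
from fishtrack3d.synthgen import SimConfig
from fishtrack3d.pipeline import run_synthetic_experiment, score_against_truth

cfg = SimConfig(duration_s=600, stress=0.0, seed=101)
res = run_synthetic_experiment(cfg)
report = score_against_truth(
    res["detections"]["front"] + res["detections"]["top"],
    res["truth"], cfg, tolerance_px=5.0,
)
print(report.accuracy, res["total_distance_mm"] / 1000.0)
```

## Layout

```
src/fishtrack3d/   synthgen, detect, fuse3d, kinematics, behav_stats,
                   frames, pipeline, plotting, cli
tests/             pytest suite incl. brute-force oracles and
                   end-to-end acceptance checks
configs/demo.yaml  four-group demo configuration
docs/methods.md    model and methods notes
```
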