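# Methods

This note documents the models, conventions and numerical choices behind
`fishtrack3d`, and what the synthetic validation does and does not show
about real recordings.

## Coordinate conventions

The tank is 540 x 370 x 400 mm (x: long side, z: short side, y: height).
Tank coordinates are right-handed with x = 0 at the left wall, y = 0 at
the floor growing upward, z = 0 at the front wall.  Image rows grow
downward, so the front-view projection flips y; that flip lives in
exactly two mirrored places (renderer projection and fusion) and nowhere
else.  Detection coordinates are 0-based sub-pixel (col, row) pairs
relative to the view's ROI origin.  The default render geometry maps
both ROIs at 1 mm/px; the calibration is nevertheless always derived
from the configured tank dimensions and ROI sizes, never assumed.

## Movement model

The simulated fish follows an attractor-biased correlated random walk
over steps of `dt = 1/fps` seconds:

```
v_t = alpha * v_{t-1} + beta * (a - p_{t-1}) * dt + eps_t,   eps_t ~ N(0, sigma^2 I)
|v_t| <- (1 - gamma) * |v_t| + gamma * s_target,             s_target = s_base * (1 + stress)
p_t = p_{t-1} + v_t * dt, reflected at the walls of the free box
```

Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `persistence_alpha` | 0.95 | directional memory; high persistence gives the smooth glide-and-turn paths typical of cruising fish at 1 Hz sampling |
| `noise_sigma` | 4.0 mm/s | per-axis velocity perturbation per step |
| `speed_relax` (gamma) | 0.5 | relaxation of the speed magnitude toward the target; direction is untouched, so speed fluctuations decorrelate much faster than headings (10-s speed means have lag-1 autocorrelation ~0, keeping the rank tests' independence assumption tenable on synthetic data) |
| `base_speed_mm_s` | 20 | cruising speed; over 10 h this yields ~0.7 km traveled, in the range reported for sub-adult tilapia in tanks of this size |
| `attractor_point` | (270, 330, 185) | center of the band just under the water surface |
| `attractor_strength_beta` | 0.25 * stress 1/s | pull toward the attractor; 0 when calm |
| `wall_margin_mm` | 70 | the walk lives in the tank shrunk by ~half a body length, so the rendered body never clips at the tank image boundary; it also stands in for the fact that a rigid body's center cannot reach a wall |
| `stress` | 0 | single knob moving the model from free cruising (full-tank occupancy) to confined agitation (small visited volume, doubled target speed) |

Reflection (not clamping) at the free-box walls avoids artificial
dwell time on boundaries.  At `stress = 1` the model visits ~7% of a
10x10x10 occupancy grid versus ~51% when calm, while total 10-h path
length roughly doubles — the confinement-plus-hyperactivity signature
the analysis is designed to detect.

## Renderer and the appearance model

Each view draws the fish as a filled ellipse (130 x 36 px by default) at
the projected centroid: the top view rotates the body to the heading
(the azimuth of horizontal velocity); the front view shows the level
side profile of a horizontal swimmer.  Pixel intensities over the body
are redrawn every frame around `fish_level` with standard deviation
`fish_texture_sd` (default 130): a live fish's appearance changes
between one-second exposures (fin posture, body flex, ripple
refraction), and this is the feature that makes frame differencing
work.  Because the silhouette interiors differ between consecutive
frames, the thresholded difference covers (most of) the **union** of the
two silhouettes.  The union of two congruent ellipses is centrally
symmetric about the midpoint of their centers, so the largest-component
centroid estimates the fish's **mid-pair position** — the frame-difference
estimand is the location at the midpoint of the two capture instants,
not at either instant.  All accuracy scoring and fusion-error metrics
therefore use the projected midpoint of the two true positions as the
reference.  With a uniform, textureless body the difference image would
instead collapse to two disjoint edge crescents whose largest component
sits half a body length away from the fish's center; appearance
fluctuation is deliberately part of the default study conditions.

Nuisance terms: per-pixel Gaussian sensor noise (sd 2), a per-frame
global flicker offset (sd 1.5), and Poisson-count bubble artifacts
(bright disks, radius 2-4 px, lasting exactly one frame) that exercise
the largest-area filter.

## Detection

The chain is crop -> grayscale -> absolute difference -> threshold
(strictly greater than 60) -> connected components (8-connectivity by
default) -> largest area with a 30 px floor -> moments.  Choices the
underlying procedure leaves open, fixed here:

- Foreground rule is strict (`pixel > threshold`); ties at the threshold
  are background.
- Connected pixel regions stand in for contours; only area and moments
  are consumed downstream, for which the representations agree.
- The area floor marks frames invalid when even the largest blob is
  implausibly small (nearly still fish), instead of tracking a bubble.
- Area ties break on the lexicographically smallest (row, col) pixel, so
  selection is deterministic.
- Centroids stay sub-pixel; rounding them would add ~0.3 mm RMS of
  quantization noise to speeds.
- Orientation is `0.5 * atan2(2*mu11, mu20 - mu02)` in [-90, 90) from
  central second moments.  The central moments are accumulated in exact
  integer arithmetic (scaled by the area) so the orientation of symmetric
  regions is well defined rather than an artifact of floating-point
  summation order.

## Fusion

Front and top detections are paired by their one-second timestamps.  The
shared x axis gives two independent estimates; a pair is accepted when
they agree within 30 mm (~ half a body length) and x is then their
arithmetic mean, which halves per-view quantization error.  Rejected or
missing seconds leave gaps; positions are never interpolated.  On clean
rendered data the accepted fraction is >= 99% and fused positions agree
with the mid-pair ground truth to ~1.8 mm RMS.

## Kinematics

Total distance sums straight-line steps between consecutive accepted
points, bridging gaps with a single step (an underestimate, never a
fabrication).  Per-second speeds divide each step by the true elapsed
time.  Binning uses nonoverlapping windows aligned to the experiment
start; a window is kept when its last covered second lies within the
observation span, so a 10-h, 1 fps recording gives exactly 3600 10-s
means and a trailing partial window is dropped.  Summaries use the
sample (n-1) standard deviation.

Two known biases of the estimator, both quantified by the acceptance
checks: mid-pair localization smooths the path (plus wall-reflection
corner cutting), recovering ~96% of the true path length at calm
defaults, and detection noise inflates it slightly; the net total-
distance error on clean 600-s runs is ~4%.

## Statistics chain

- **KS normality screen:** one-sample Kolmogorov-Smirnov distance to a
  moment-matched normal, p from the asymptotic Kolmogorov distribution
  of `sqrt(n) * D`.  With estimated parameters this is anticonservative
  (the Lilliefors effect); a seeded Monte-Carlo Lilliefors variant is
  available (`method="monte-carlo"`).  The screen is reported, not used
  to gate the rank tests.
- **Kruskal-Wallis:** mid-ranks for ties; tie-corrected H; chi-square
  p with k-1 df.  Fully tied data are defined as H = 0, p = 1 rather
  than a division by zero.
- **Dunn post hoc**, run only when Kruskal-Wallis is significant at
  alpha: tie-corrected rank variance, two-sided normal p-values,
  Bonferroni multiplication by all k(k-1)/2 comparisons capped at 1.
- **Diagnostic:** binned speeds from one recording are serially
  dependent in general, which rank tests ignore; the report carries each
  group's lag-1 autocorrelation so users can judge the violation.  Under
  the synthetic defaults the 10-s bins are nearly uncorrelated and the
  Kruskal-Wallis gate's measured type-I error is compatible with the
  nominal 5% (200-replicate check).

## Validation harness

Accuracy is scored the way a manual audit would: a seeded simple random
sample of frame pairs, each counted correct when the detection is valid,
the fish visible, and the marked point within `tolerance_px` (default
5 px) of the projected mid-pair truth.  Problem sizes used by the
automated checks: 200 random binary images for the image-core oracle,
100 random datasets for the statistics oracle, 600-s dual-view renders
(1201 frame pairs) for end-to-end recovery, 200 null and 20 shifted
replicates of four 10-h speed series for calibration and power, and 20
paired 10-h simulations for the stress contrast.

## What the synthetic validation does not show

The generator emulates the acquisition geometry and the statistical
structure the analysis assumes — it is not a fish.  Real recordings add
water-surface glare, shadows, reflections at the glass, occlusion by
equipment, exposure drift, fish shape change (turning in depth), and
bouts of true immobility, none of which are modeled; real per-second
speed distributions are burstier (idle periods and darts) than the
model's near-normal speeds, so the KS screen rejecting normality on real
data but not on synthetic data is expected.  Passing the synthetic
checks shows the measurement chain is correct and calibrated under its
stated assumptions, not that the detector is robust to every real-world
nuisance.
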