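# Methods

This note records the models behind `otokit`'s synthetic generators and
analysis defaults, the numerical choices that affect results, and what the
synthetic studies do and do not demonstrate about real data.

## μCT phantom

The otoconial mass is modelled as an ellipsoid of constant CT number
`mu_otolith` (default 200) in a background of `mu_background` (default 50),
sampled on a (z, y, x) voxel grid (default 72³ at 5 μm isotropic; physical
coordinate = index × spacing + origin). Defaults place a 100 × 60 × 40 μm
semi-axis ellipsoid at the grid centre. The striola is a planar channel of
width `striola_width_um` through the centre, normal to the longest
semi-axis, in which density is reduced by `striola_depth` of the contrast —
the simplest geometry that shows the central low-density band and gives the
dual-threshold edge statistic something to measure. The noiseless field is
smoothed with a Gaussian of physical scale `edge_blur_um`, then i.i.d.
Gaussian noise (`noise_sd`, default 5 ≈ 1/30 of the contrast) is added.
Ground truth (masks, voxelized volume, pre-blur mean CT) is recorded before
blur and noise.

Boundary blur is the aging knob: a young, intact striola boundary is a
near-step transition, an aged one a gentle ramp. Defaults therefore use
`edge_blur_um = 0` (sharp) and no striola; two presets cover the striola
studies:

* `striola_preset()` — default grid, 30 μm channel at depth 0.9 (a thin
  density residue remains). Depth 0.9 keeps the channel interior well below
  the edge band `[0.9 T, T)`, so the channel appears as a central gap in
  the supra-threshold model and the band is populated only by boundary
  voxels.
* `edge_study_preset()` — 2.5 μm voxels, a 150 × 100 × 60 μm mass and a
  60 μm channel. The finer grid resolves 2 μm blur (sub-voxel at 5 μm
  spacing), and the larger mass keeps its density plateau intact at 16 μm
  blur; with the default geometry the edge volume would saturate and then
  shrink at the top of the blur range. With this preset the edge volume
  rises strictly monotonically over blur scales 0–16 μm.

ROIs mimic manual placement: the otolith ROI is the ellipsoid dilated by
`roi_margin_um` (default 5 μm, one voxel — a rater circles the bright spot
snugly; large dilations of a sub-millimetre object mostly add background
and dilute α), and the tissue ROI is a background shell 30–60 μm from the
surface. Distances are Euclidean in μm, so anisotropic grids are handled.

α and β are arithmetic means of their ROIs by default; a histogram-mode
summary is available (`summary="mode"`), which is insensitive to ROI
dilution but quantized to the bin width. The threshold is always computed
per specimen from its own ROIs, so specimens with different absolute CT
scales are comparable.

Segmentation is a pure voxel-wise rule (CT ≥ T within the ROI). Connected
component filtering (26-neighbourhood, the standard for bright 3D objects)
is off by default and on in the CLI preset; note that a deep striola
channel can sever the mass into two components, in which case
`keep_largest` reports only the larger half. The edge set is the literal
set difference segment(0.9 T) \ segment(T) with the same component policy
on both sides; without component filtering it equals the band
`{0.9 T ≤ CT < T}` exactly, which is what the oracle-equivalence tests
assert.

## Sled and eye model

Sled legs are pure trapezoidal-velocity moves: accelerate at `a_max`,
cruise at `v_max`, decelerate at `a_max`, covering `distance_m` (default
1.8 m); feasibility requires v²/a ≤ d. No jerk limiting — the two stated
maxima are attained exactly, which is the minimal profile realizing both.
Stimulus levels: 1.3 G (12.753 m/s², g = 9.81) with 3.25 m/s, and 0.7 G
with 3.06 m/s. Five round trips with 0.3 s dwells at each end, sampled at
240 Hz. Dwells contribute exactly `round(0.3 × 240) = 72` zero-velocity
samples; legs are sampled strictly inside the motion interval on the 1/rate
grid, so the sub-sample remainder of a leg (< one sample's travel, here
≲ 0.1 mm) is absorbed at the junction to the dwell. The analytic velocity
and acceleration channels are stored alongside position; `derive_kinematics`
reconstructs them from position alone (zero-phase moving average, default
window 5, then centred differences — exact within constant-acceleration
phases) for data that arrive as marker positions only.

The eye model is linear and lag-free: vertical component
`y(t) = gain × a(t)/g + drift × t + noise`, torsional and horizontal
components noise-only, positive acceleration producing a positive vertical
shift of the left eye. Real LVOR responses have latency and mild
nonlinearity; an optional `lag_s` (integer-sample shift) is provided, but
no dynamics are modelled — gain-recovery results show the *analysis* is
unbiased, not that real eyes are linear.

## Cycle segmentation and function index

Dwells are detected as maximal runs with |v| ≤ 20 mm/s lasting ≥ 0.25 s
(robust against the 72-sample true dwells; both thresholds configurable).
One cycle spans one round trip: from the start of motion after an even-
numbered (home-end) dwell to the start of motion after the next home-end
dwell. Five reciprocations therefore yield exactly five cycles.

The baseline ("eye at rest") is the mean vertical component over all dwell
samples. Per cycle the index is half the peak-to-peak excursion of the
vertical component about that baseline; the function index averages the
three largest of the five cycles. Before peak-picking, the vertical trace
is smoothed with a zero-phase moving average (default 41 samples ≈ 0.17 s
at 240 Hz, settable to 1): the raw extremum over ~120 plateau samples
exceeds the true plateau by roughly 2.9 noise standard deviations
(≈ +0.14° at 0.05° noise), a bias that would dominate at low gains, while
the stimulus' acceleration plateaus (≥ 61 samples) are longer than the
window, so the true excursion passes through unattenuated. The max/min
search includes dwell samples by default (`exclude_dwells` is available);
with an offset-free trace the dwell values sit near baseline and do not
affect the extrema.

## Layer angle

Each traced point set is reduced to a line by total least squares
(principal axis of the centred scatter), which is invariant to the axis
orientation of the tracing — ordinary regression is not. The angle between
the two directions is computed as `atan2(|d₁ × d₂|, |d₁ · d₂|)`, which is
well conditioned for near-parallel and near-perpendicular lines (arccos of
the dot product loses half the available precision near 0°) and folds the
result into [0°, 90°]. Fewer than two distinct points is a degenerate
input. The generator places both lines through the origin with isotropic
Gaussian jitter; tracings are taken as given — extracting them from
micrographs is out of scope.

## Cohort model and statistics

Cohorts are per-ear records in a 2 × 2 age (young/old) × sex design with
additive cell effects and homoscedastic Gaussian residuals — exactly the
structure the parametric pathway assumes, which is what makes the
calibration studies interpretable. Ears are treated as independent
observations (two per mouse), mirroring the convention of analyzing n ears
rather than nesting within animal. Default effect directions follow the
aging phenotype: lower density and function index, larger edge volume,
smaller layer angle in old ears.

The ANOVA uses Type III sums of squares with sum-to-zero contrasts (the
SPSS convention; Type II by flag), so mildly unbalanced designs — e.g. one
lost animal — are handled. The normality screen (Shapiro–Wilk plus a
Kolmogorov–Smirnov test against a normal with sample-estimated moments)
warns and proceeds on failure rather than aborting; a rank-based fallback
is deliberately not silently substituted. The Bonferroni post-hoc runs
when the interaction p < 0.05 (or always/never by flag), with family size
m = 6 (all pairs of four cells) by default and m = 4 (the conventionally
reported within-age and within-sex contrasts) selectable; adjusted
p = min(1, m × raw). Significance is fixed at 0.05 throughout.

## Problem sizes and calibration checks

The test suite and `scripts/acceptance.py` use: 72³ default phantoms and
the 176 × 136 × 104 edge-study grid; 100 random ≤ 16³ volumes for exact
oracle equivalence against a brute-force voxel scan; one 5-round-trip sled
trace per stimulus level; 400 null cohort replicates (n = 10 per cell) for
the ANOVA type-I error and 200 replicates for power at an age effect of
2 residual sd. These sizes give stable estimates (binomial CI half-width
≈ 0.021 on the null rejection rate) while keeping a full run to a few
minutes on one CPU.

## Known limitations

* Phantoms are ellipsoids with a planar striola; real maculae are curved
  shells with spatially varying otoconial thickness. Recovery results
  validate the measurement chain, not anatomical realism.
* The eye model omits latency, habituation and torsional cross-coupling;
  only the vertical component is analyzed.
* CT numbers are relative (no Hounsfield calibration); all comparisons are
  within-scale, via the per-specimen α/β threshold.
* No mixed-effects modelling of ear-within-mouse correlation; cohort
  inference matches the ears-as-independent convention.
* NIfTI voxel sizes are interpreted as micrometres (written with micron
  units); volumes from other software with millimetre zooms need a
  spacing sidecar or rescaling.
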