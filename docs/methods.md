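# Methods

This note records the models behind `mitodyn`, the parameters that matter,
the choices made where the underlying procedures are conventionally left
unspecified, and what the synthetic benchmarks do and do not demonstrate.

## Transport model and preset calibration

A movie contains `n` organelles on a straight horizontal axon with the
soma at coordinate 0 (anterograde = increasing position). Each organelle
is mobile with probability `mobile_fraction` (Bernoulli per organelle, so
the realized mobile count varies binomially between movies, as between
biological fields). A mobile organelle draws a constant run speed `v` from
a Normal(μ, σ) truncated to `[v_lo, v_max]` and a fixed direction
(retrograde with probability `retrograde_fraction`); on each frame
interval it either advances `v·Δt` or pauses, with per-frame pause
probability `p`. Stationary organelles wobble around their anchor with
sub-pixel Gaussian jitter (σ = 0.1 px), so they are not artificially
perfect. Under this model the expected overall velocity of a mobile track
is `v·(1−p)` and the expected cohort mean over all organelles is
`mobile_fraction · E[v] · (1−p)`.

Calibration inverts that relation: for each condition preset the target
cohort mean (e.g. 0.021 μm/s for wt at 7 DIV) fixes the required `E[v]`,
and μ is solved numerically from the truncated-normal mean on the actual
support. Two support choices matter:

- `v_lo = 2 × 0.005/(1−p) μm/s`: run speeds are bounded away from the
  mobility threshold so that essentially every mobile organelle is
  *classifiable* as mobile. The printed instantaneous velocities are
  conditional on that classification, so `E[v]` is only their calibration
  target when the sub-threshold mass is negligible. Biologically this says
  motor-driven runs are distinctly faster than the classification floor.
- `v_max = (axon_length − 6 μm)/duration`: every mobile organelle is
  placed with enough runway that its full pause-free excursion stays ≥2 μm
  inside the field, so no boundary clipping biases the cohort mean. Axon
  lengths per preset are sized so this cap sits ≳2.5 σ above the mean run
  speed (e.g. 650 μm for the fast 14 DIV condition).

The instantaneous-velocity targets and the two-state structure jointly pin
the remaining parameters. For wt 7 DIV: instantaneous 0.051 μm/s = `E[v]`,
cohort 0.021 μm/s, hence `mobile_fraction·(1−p) = 0.41`. A consistency
constraint follows: with exactly 30% mobile the mobile-mean overall
velocity would exceed the instantaneous velocity, which is impossible
(net displacement ≤ path-integrated motion). The wt presets therefore use
`mobile_fraction = 0.45` (the mobile fraction of wt neurons is reported as
">30%", which this satisfies) and `p = 0.085`. Where no instantaneous
value is reported the same `p` is reused.

Run-speed σ per preset is chosen so the synthetic cohort SEM approximates
the reported SEM (per-particle SD = SEM·√n). This matters for inference,
not just realism: the wt (0.050 ± 0.010, n = 58) vs A53T + rapamycin
(0.075 ± 0.023, n = 130) comparison is non-significant precisely because
the per-organelle spread is large (expected t ≈ 1); with narrow speed
distributions the same means would separate. One preset cannot be matched
exactly: the A53T 7 DIV SEM (0.001) is below the variance floor of any
mobile/stationary mixture with that mean and ~8% mobility, so its σ is set
to a 30% coefficient of variation and the synthetic SEM (~0.0015) is
slightly larger than reported.

Rendering: Gaussian puncta (σ = 1.5 px, peak ≈ 400 a.u. with ±25%
per-organelle variation) on a constant background (100 a.u.) with additive
Gaussian read noise (σ = 20 a.u.), quantized to uint16. The noise level is
a choice, not a measured camera model; it yields SNR ≈ 15–20, at which
centroid noise (~0.05 px) contributes negligibly to frame-to-frame speeds.
Imaging geometry defaults to the study conditions: 3 s intervals, 101
frames (5 min), 0.1–0.2 μm/px.

## Detection and linking

Detection is difference-of-Gaussians band-pass (σ₁ = psf, σ₂ = 2.5 psf),
5×5 local maxima above 5 robust SDs of the response, and intensity-weighted
sub-pixel centroids in a 7-px window. Linking is greedy global
nearest-neighbour with three refinements that exist because organelles on
an axon genuinely pass each other:

1. **Velocity prediction.** Candidate cost is the distance to the track's
   constant-velocity extrapolation (EMA of per-frame displacement), so a
   moving track prefers its own continuation over a stationary neighbour.
2. **Occlusion sharing.** When two puncta merge into one detection, the
   track that lost the assignment contest shares the merged detection
   (within an 8 px radius) instead of dying; both identities coast through
   the occlusion with frozen velocity estimates (the winner's velocity
   update is rolled back too, since the blended centroid is not a real
   motion observation). The frozen velocities are what re-separate the
   identities correctly when the puncta split.
3. **Deterministic tie-breaking** by (cost, track index), and gap closing
   up to 2 skipped frames with a gate of `max_step` μm per elapsed frame.

Tracks shorter than 5 observations are discarded. Detections optionally
carry an integrated-intensity column and the linker accepts an intensity
mismatch penalty, but the default weight is 0: in dense fields the
band-pass mass of nearby puncta cross-contaminates, and in benchmarks the
penalty caused more identity errors than it fixed.

Residual limitation: crossings still occasionally fragment or swap tracks.
On the wt 7 DIV benchmark ≈95% of organelles are recovered with the
correct mobility label, recovered cohort means sit within ~5% of truth,
and the recovered mobile fraction runs ~2–4 percentage points high
(mobile-track fragments count twice). Statistics that average per-track
velocities are robust to this because fragments inherit the parent's
velocity; count-based statistics are the ones to treat with care at high
density. The binomial-recovery property test therefore uses a low-density
preset — its purpose is to verify the estimator is unbiased in the regime
the detector/linker are designed for, not to hide the density effect,
which is documented here.

## Morphometry

Segmentation is a global Otsu threshold (config-overridable to a fixed
value; the choice of thresholding method is conventionally silent in
morphometry macros), 8-connectivity, minimum area 0.1 μm². Objects
touching the image border are flagged and excluded from summaries, as are
touching objects — via the generator's truth flag on synthetic data, or an
area > mean + 3 SD rule on real data (merged pairs are large).

Axes come from the second-moment best-fit ellipse (`regionprops`). The
perimeter is the length of the marching-squares half-level contour after
circular moving-average smoothing (window 5 contour points): the raw
staircase contour overestimates a disc's perimeter by ~7% and naive
pixel-edge counting by more, whereas the smoothed estimator is accurate to
~1% for discs of radius 5–30 px and keeps the circularity of a 20 px disc
within 2% of 1. Rotation changes the rasterization itself, so circularity
is rotation-stable to ~2% only for objects more than ~20 px across; the
smallest synthetic mitochondria (<1 μm at 0.1 μm/px) carry proportionally
larger rasterization noise.

The morphology generator renders rotated filled ellipses (lengths
truncated-normal, mean 1.96/1.32 μm for the two conditions, aspect ratio
~3), blurred with a 1 px PSF, on a 51 μm field of 40 objects placed with
enforced clearance; `overlap_fraction` deliberately places
`floor(f·n/2)` touching pairs to exercise the exclusion logic.

## Membrane potential

ROIs are supplied (generator truth or user polygons); soma segmentation is
out of scope because cytosolic areas are conventionally outlined by hand.
Background subtraction (mode of the non-ROI pixels) is available but off
by default. Normalization divides by the mean of the designated control
group within the run, so the control group reports exactly 100% and the
result is invariant to global intensity rescaling. No mV calibration is
attempted; dye intensity is a relative ψ_m proxy only.

## Bioenergetics

Phase summaries are arithmetic means of that phase's readings — including
the FCCP phase (mean, not peak, of its 3 readings; the plateau model makes
the distinction immaterial on synthetic data, and the mean is the less
noise-chasing choice on real data). Negative derived values, which arise
under measurement noise, are reported with a QC warning rather than
clipped, so the `mitochondrial = ATP-linked + leak` identity remains exact
by construction. The rotenone/antimycin-only schedule yields a partial
profile (non-mitochondrial and mitochondrial respiration); absent fields
are `None`, never imputed. Trace times use a 6.5 min measurement cadence;
ECAR rises 40% after oligomycin (glycolytic compensation) — both are
generator conventions, not measured values.

Flux preset components (wt: ATP-linked 107.0, leak 25.3, non-mito 28.0,
FCCP plateau 300; A53T: 101.0, 26.1, 42.0, 230; pmol/min per 40,000
cells) are constrained by the two reported basal values (160.3, 169.1) and
by the reported direction of every group difference (A53T lower ATP-linked
and maximal capacity, higher non-mitochondrial, similar leak, more
glycolytic); the individual splits within those constraints are choices.

## Statistics

Summaries are mean ± SEM with the n−1 denominator; n = 1 reports SEM 0
with an explicit flag. The default two-sample test is Student's pooled-
variance t (Welch available by flag), two-sided, with no multiple-testing
correction — matching the reporting conventions the pipeline emulates.
Under the null (same preset, different seeds) pipeline p-values are
uniform; this holds because mobility is Bernoulli per organelle — with a
fixed mobile count per movie the dominant variance component would vanish
and the t-test would be conservative.

## Pipeline determinism and problem sizes

All stage randomness derives from the run seed through a fixed affine map,
and every CSV is written with a fixed float format, so identical config +
seed reproduce identical bytes. The test suite exercises reduced cohorts
(typically 4–6 movies per condition, low-density presets for property
tests); `scripts/acceptance.py` uses 20 movies per transport condition, 3
autophagosome movies (~309 pooled tracks), 20 morphology fields, and the
noise-free flux trace. These sizes give sampling error comfortably inside
the 2-SEM bands used for verification.

## What the benchmarks do not show

The generator emulates straight axons, constant-speed runs, additive
Gaussian noise, and non-interacting puncta. Real recordings add curved
axons (handled by the polyline kymograph path but not exercised by the
presets), photobleaching, focus drift, fission/fusion (excluded by design,
matching the source protocol's selection of non-dividing mitochondria),
speed variation within runs, and non-Gaussian camera noise. Passing the
synthetic benchmarks therefore demonstrates correctness of the measurement
chain under the stated model, not robustness to all microscopy artifacts;
the detector threshold and linker gates are the parameters to revisit
first on real data.
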