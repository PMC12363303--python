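# Methods

`blebmetrics` quantifies large-volume subcutaneous (SC) injections from two
data streams: a timed series of CT-like volumes in which the injectate is
visible as a high-intensity bleb (an iodinated-contrast surrogate), and an
inline pressure recording from the injection line. This note describes the
models, the synthetic data the package is validated on, the numerical
choices, and the limitations of each.

## Bleb morphometry

**Segmentation.** The contrast-loaded bleb sits thousands of HU above soft
tissue, so segmentation is seeded connected-component thresholding: voxels
at or above a threshold are labelled, the component containing a
user-supplied seed voxel is kept (26-connectivity by default), and one
binary-closing pass (6-connected ball, radius 1 voxel) fills pinhole
noise — the automated analogue of threshold-plus-manual-touch-up
segmentation in clinical viewers. The `"auto"` threshold is the midpoint
between the modal intensity of the whole volume (background; with a
slab-plus-air field of view this is air) and the median of a 5×5×5
neighbourhood around the seed. This is robust precisely because the
injectate is engineered to be high-contrast; it is not suitable for
low-contrast injectates.

**Ellipsoid summary.** The bleb is summarized as an ellipsoid. The
semi-axes *a* ≥ *b* ≥ *c* are half the axis-aligned extents of the mask per
grid axis (`(max − min + 1) · spacing / 2`), matching the on-screen bracket
measurements this analysis automates — *not* PCA axes. Surface area uses
the symmetric p-norm approximation

S = 4π [ ((ab)^p + (ac)^p + (bc)^p) / 3 ]^(1/p),  p = 1.6,

exact for spheres and, against an independent Gauss–Legendre quadrature of
the surface integral, within 2% for aspect ratios up to 10 (the test grid);
the classical constant 1.6075 reduces the worst-case error slightly and is
available via the `p` argument. Surface area is deliberately computed from
three axis measurements rather than a 3-D mesh: for regular blebs this is
less sensitive to inter-slice interpolation, and irregular blebs are out of
scope. Mask volume (voxel count × voxel volume) serves as a sanity check
against the injected volume.

## Skin distension

Distension — the skin raised above its pre-injection surface — is obvious
on a pre/post overlay but hard to threshold from a single image. It is
quantified as a surface difference: the skin surface of each scan is
extracted as a depth map (first voxel ≥ −500 HU per lateral column,
scanning from the exterior along the depth axis), the protrusion height is
`pre depth − post depth`, and the largest connected lateral region with
height ≥ `min_height` (default 0.5 mm, half a typical voxel) is modelled as
a half-ellipsoid:

V = (2/3) π a b c,

with *a*, *b* half the lateral extents of the region and *c* its peak
height. The thresholded footprint slightly shrinks the lateral extents (by
design: the analytic footprint at height 0.5 mm of a 4 mm cap is 0.8%
narrower), which is why volume recovery is validated at 15% while the
individual dimensions recover within one voxel.

No registration is performed; the acquisition protocol this mirrors
suppressed respiration during scanning. `check_alignment` verifies the
assumption: the mean absolute pre/post intensity difference outside the
bleb+cap region, normalized by the noise s.d. (perfectly aligned
independent scans score 2/√π ≈ 1.13; the default gate is 2.0).

The plateau summary averages the half-ellipsoid volumes over a closed
90–120 s post-injection window (configurable).

## Pressure analysis

The pump stop time follows from the protocol, `t_cess = t_start +
volume / flow rate` (27 s and 54 s for 4.5 and 9 mL at 10 mL/min). Peak
pressure is the maximum sample in the closed window `t_cess ± 2 s` (ties →
earliest sample). The post-injection decay over the 2 min after the peak is
fit by nonlinear least squares to

P(τ) = baseline + A₁ e^(−k₁τ) + A₂ e^(−k₂τ),  A₁, A₂ ≥ 0, k₁ ≥ k₂ > 0,

a fast component (line/tissue elastic recoil) plus a slow one (fluid
redistribution through the SC matrix). The single-number summary is the
amplitude-weighted mean rate

k_eff = (A₁k₁ + A₂k₂) / (A₁ + A₂),

which always lies in [k₂, k₁].

Numerical choices that matter:

* **Baseline.** A constant offset is estimated jointly by default (real
  gauges rest above zero); it can be pinned to a known value. Decay-rate
  estimates are invariant to baseline shifts.
* **Fit clock and window.** τ = 0 at `max(t_peak, t_cess)`: the decay
  cannot begin before the pump stops, and a noise-inflated peak detected
  slightly before cessation must not pull rising-phase samples into the
  fit. The peak sample itself is included — it anchors the total amplitude
  A₁+A₂, which is otherwise an extrapolation and noticeably noisier.
* **Initialisation.** Curve peeling: the baseline is seeded 5% of the
  signal range below the window minimum (keeping the tail residual strictly
  positive and log-linear), the slow component is log-linear-fit on the
  50–90% segment of the window, the fast one on the early residual; five
  seeded, jittered restarts guard against local minima. At 10 Hz a 120 s
  window holds 1200 samples; at least 50 are required.
* **Degenerate inputs.** A flat trace converges to A₁ = A₂ ≈ 0 and is
  flagged non-identifiable (amplitudes below 1 µPa count as zero); k_eff is
  undefined there. Single-exponential traces fit with either A₂ ≈ 0 or
  k₁ ≈ k₂; k_eff is stable under this ambiguity, which is why it is the
  reported endpoint.

Pressures are kPa throughout; psi and mmHg are converted on read.

## Synthetic data

No imaging or pressure data from the original study are available, so the
generator produces ground-truth-labelled stand-ins with the statistical
structure the analysis assumes.

**Phantoms.** Anatomy is reduced to flat slabs along the depth axis
(exterior air at −1000 HU, a 2 mm skin slab, a subcutaneous slab, deep
tissue), with the bleb rasterized as an ellipsoid of `contrast_hu` (default
3000, emulating undiluted iodinated contrast) and the skin surface raised
by a half-ellipsoidal cap profile. Defaults: 72×64×48 voxels at 1 mm
(anisotropic spacing supported, e.g. 3 mm slices), 4.5 mL-scale bleb
(16, 12, 5.6) mm, cap (12, 10, 3.5) mm, 20 HU i.i.d. Gaussian noise with
`contrast > background + 5·noise_sd` enforced. Bleb growth over the scan
schedule (baseline, 5, 30, 60, 90, 120, 180, 600 s) follows saturating
kinetics `axis(t) = a₀ + Δ(1 − e^(−t/τ))` with default Δ = (3, 3, 0.5) mm,
τ = 120 s; a hyaluronidase factor ≥ 1 multiplies lateral growth and divides
cap height (the enzyme spreads the depot laterally and flattens the bulge).
No quantitative dispersion kinetics were available to calibrate against, so
these are plausibility choices, not fitted values.

What the phantoms do *not* emulate: curved anatomy, CT physics (beam
hardening, partial volume), correlated noise textures, respiratory motion,
irregular bleb shapes. Passing recovery tests therefore demonstrates the
correctness of the measurement chain, not robustness to those real-data
effects.

**Pressure traces.** 10 Hz sampling; a linear ramp from baseline to
baseline + A₁ + A₂ during the infusion (constant-flow pump), optionally a
first-order rise (inline sensors split off the injection line rise more
slowly early in the injection); after cessation, the same two-component
exponential the analysis fits, plus i.i.d. Gaussian noise. The trace is
continuous at cessation by construction. Defaults A₁ = 10, A₂ = 5 kPa,
k₁ = 0.5, k₂ = 0.05 s⁻¹ give peak-scale pressures and a decay that retains
both components within the 2 min window.

## Study pipeline

`run_experiment` replicates the design: arms of (4.5, 9 mL) × (±HLN) with
n = 3, full scan schedule, one pressure trace per replicate. Endpoints per
replicate: bleb surface area at the 600 s scan (10 min post-injection),
distension volume averaged over 90–120 s, peak pressure, k_eff. Injected
volume scales the bleb/cap templates with the cube root of volume; HLN
multiplies lateral dispersion by 1.5 and pressure amplitudes by 0.6.
Replicates get lognormal size jitter (CV 2%) on bleb/cap axes and pressure
amplitudes — inter-animal variability, without which imaging endpoints
would be identical within an arm; the CV is kept small relative to the HLN
effect, consistent with a design in which n = 3 per arm can reach
significance.

Group statistics follow the original reporting: per-arm mean ± sample s.d.
and two-sided two-sample Student's t-tests (pooled variance, α = 0.05, no
multiple-testing correction; Welch available via `welch=True`). Degenerate
zero-variance comparisons (possible for voxel-quantized distension
endpoints) are recorded as notices rather than aborting the run. The
t-test's type-I error is calibrated under null-configured arms (identical
generators, distinct seeds, n = 20, endpoint = peak pressure of a noisy
trace): nominally 5%, with ±1% Monte Carlo error at the 500-experiment
calibration size.

## Problem sizes

Validation uses 72×64×48-voxel phantoms (eight-scan series for pipeline
runs), 100-trace batches for noisy fit recovery, and 500 simulated
experiments for t-test calibration; a full four-arm study with n = 3 runs
in a few seconds on one core.

## Known limitations

* Axis-aligned extents under-/over-estimate semi-axes of blebs oriented
  obliquely to the grid; a PCA-aligned variant is not provided.
* The skin-surface extractor assumes the exterior is reached along the
  depth axis; strongly folded surfaces (overhangs) are not representable in
  a height map.
* The distension threshold `min_height` must exceed one voxel-equivalent of
  surface noise to avoid false positives; the default assumes ≲1 mm voxels.
* The decay model fixes two components; fits to traces with slower
  multi-compartment behaviour fold the extra components into k₂.
* Absolute pressure calibration (sensor offset, line compliance) is out of
  scope; comparisons across arms assume a shared measurement chain.
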