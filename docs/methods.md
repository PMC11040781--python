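# Methods

## Scope and model

The package treats a scattering study of cellulosic material as a pipeline
with three layers:

1. **Reduction.** 2D pinhole detector images are azimuthally integrated to
   1D *I*(*q*) profiles; profiles are normalized to per-second units,
   background-corrected against an empty-holder measurement, and averaged
   over parallel replicates.
2. **Per-sample analysis.** WAXS profiles are decomposed into crystalline
   and amorphous Gaussians; SAXS profiles are reduced to the Kratky-peak
   position and hence the mean center-to-center microfibril distance.
3. **Study statistics.** Per-condition replicate aggregates, percent change
   versus a named reference condition, and two-tailed t-tests.

All internal units are Å⁻¹ for *q* and Å for lengths; nm appears only in
reported values (factor 10). Both conversion formulas are the field's
small-angle conventions: Bragg *d* = 2π/*q*ₘₐₓ and Scherrer
*L* = 2π/Δ*q* with shape factor 1 and no instrumental-broadening
correction.

## Reduction layer

**Geometry.** Flat detector at normal incidence: a pixel at radial distance
*r* (mm) from the beam center scatters at 2θ = arctan(*r*/distance) and
*q* = (4π/λ)·sin θ, with λ = 1.542 Å (Cu Kα) by default. Pixel centers sit
at integer + 0.5 pixel units; the beam center is fractional; radii are
center-to-center. Default instrument constants: 55 mm sample–detector
distance for WAXS (exposure 2400 s, flux factor 1) and 600 mm for SAXS
(exposure 1000 s, flux factor 4.5 — the small-angle beam of the emulated
instrument is 4.5× more intense to offset shorter acquisitions).

**Integration.** Unmasked pixels are mean-aggregated into equal-width *q*
bins; empty bins are dropped; bin uncertainty is √(Σ counts)/*n*
(Poisson). No solid-angle or polarization correction is applied — the
reduction is a plain azimuthal average, which is exact for the isotropic
(randomly oriented fiber) samples it models. The integrator is verified in
the test suite against an independent per-pixel brute-force loop.

**Normalization and background.** Per-second units are counts divided by
exposure × flux factor; the operation records itself on the object and a
second application is an error, so accidental double normalization cannot
occur silently. Empty-holder subtraction interpolates the background
linearly onto the sample grid (extrapolation forbidden; ≥ 90% q-overlap
required), defaults to scale 1.0 (no transmission measurement is modelled),
retains negative residuals and counts them as a diagnostic. Subtraction
order (2D images vs 1D profiles) is the user's choice; 1D is the default
path. Replicate averaging reports the pointwise *n*−1 standard deviation as
the uncertainty band.

## WAXS decomposition

Five Gaussians — crystalline 1-10, 110, 102, 200 plus one broad amorphous
component — are fitted simultaneously by Levenberg–Marquardt (lmfit) over a
0.7–2.0 Å⁻¹ window. Gaussians are parameterized by (height, center, FWHM)
with σ = FWHM/2.3548 internally. Default initial centers are the standard
cellulose Iβ assignments 1.05, 1.17, 1.46, 1.60 Å⁻¹ with the amorphous halo
at 1.35 Å⁻¹ (FWHM 0.6); all are config-overridable. Constraints: centers
within ±0.15 Å⁻¹ of their initialization, FWHM in [0.01, 1.5] Å⁻¹,
amplitudes ≥ 0, and the amorphous FWHM ≥ 2× the widest crystalline FWHM
(implemented as a non-negative excess over that bound, so it holds exactly
during optimization). Parameters finishing pinned at a bound are recorded
as warnings rather than failures.

The crystallinity index is Σ(crystalline Gaussian areas) divided by the
trapezoidal area under the **observed** intensity over the fit window;
using the modelled total instead is available behind a flag. The ratio is
clamped to [0, 1] with a warning if it exceeds 1 (possible when the fit
window truncates peak tails). The amorphous component is modelled as a
single Gaussian — a deliberate simplification; real amorphous halos are
not exactly Gaussian, and the denominator window is itself a convention
exposed as configuration.

## SAXS reduction

Background: *A·q*⁻ᵅ with α fixed at 4 (dry samples; a free-α log–log fit
exists for wet samples) is fitted by linear least squares on a low-*q*
window (default 0.010–0.030 Å⁻¹); the constant is the **median** of the
power-law-subtracted intensity over a high-*q* window (default
0.25–0.30 Å⁻¹) — median rather than mean for robustness to residual peak
tails — after which *A* is refined once with the constant removed. Both
windows are conventions of this implementation and are config-overridable.

The Kratky curve *q*²·*I* of the subtracted profile is searched for a peak
over 0.05–0.25 Å⁻¹: the initial center is the argmax of a 5-point
moving-average smoothing (smoothing is used only for initialization), ties
resolve to the lowest-*q* maximum and flag the result ambiguous, and a
curve with no interior maximum raises a no-peak error. The Gaussian is then
fitted in Kratky space (not intensity space) locally over center ±
max(2×FWHM-guess, 0.05 Å⁻¹); a fitted center at the local window edge is
flagged. Finally *d*_cc = 2π/*q*_peak; the identity *d*_cc·*q*_peak = 2π
holds exactly by construction.

## Statistics

Replicate aggregation uses the sample (*n*−1) standard deviation; a single
replicate has undefined sd (reported as missing, never as 0). The t-test
defaults to Welch's unequal-variance form — the classical Student variant
is selectable — with two-tailed *p* and significance fixed at *p* ≤ 0.05;
no multiple-testing correction is applied to the per-measure comparisons.
The degenerate zero-variance/equal-means case returns *p* = 1 by
convention. Percent change is 100·(mean_t − mean_r)/mean_r, signed.
Percent-bound clamps to [0, 100]; standard-curve quantification is an OLS
line from absorbance to concentration that flags (never silently accepts)
extrapolation beyond the calibrated range.

## Synthetic data: what it emulates, what it does not

The generators sample the same model families the analysis fits — that is
the point: with noiseless input, recovery is exact by construction, so any
estimator error isolates the effect of noise, windowing and initialization
rather than model mismatch. Defaults define the reference study
conditions:

* SAXS truth: *d*_cc = 40 Å (*q*_peak ≈ 0.157 Å⁻¹, within the 3–5 nm
  fibril-packing scale), background *A* = 2×10⁻³, α = 4, *c* = 0.5, packing
  peak Gaussian in Kratky space with FWHM 0.06 Å⁻¹ and unit Kratky
  amplitude; grid 400 points over 0.01–0.3 Å⁻¹.
* WAXS truth: the default Iβ centers above with FWHMs 0.09–0.12 Å⁻¹ and
  relative amplitudes 0.6/0.9/0.4/1.0 (200 strongest); the amorphous
  amplitude is solved in closed form so the analytic crystallinity index
  over the fit window equals the target (default 0.55); grid 800 points
  over 0.1–3.0 Å⁻¹.
* Noise: multiplicative Gaussian, default fraction 1%; Poisson sampling is
  reserved for detector-image counts.
* Studies: 3 replicates per condition; the treated condition's *q*_peak is
  divided by (1 + spacing increase), default 0.22, so the true spacing
  grows by exactly that fraction. Replicate-to-replicate variation (default
  1%) jitters the SAXS *q*_peak multiplicatively; on the WAXS side one
  shared draw per replicate scales all centers and one all widths (a
  sample's whole diffraction pattern shifts coherently) at a tenth of the
  jitter, with per-reflection amplitude jitter at the full value. The
  treatment never modifies the WAXS truth — it is a spacing-only effect.

A real-space-Gaussian peak (instead of Kratky-space) can be constructed
directly via `SyntheticTruth` to probe model mismatch. What the simulations
do **not** contain: multi-phase backgrounds, detector artifacts, preferred
orientation, paracrystalline disorder, or any physical lattice model of
fibril packing. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated model, not robustness to every feature
of real pulp data.

## Numerical choices and problem sizes

Fits run Levenberg–Marquardt with analytic-free residuals; tolerances are
lmfit defaults. Background fitting is linear algebra, not iterative.
Degenerate inputs fail loudly: flat WAXS profiles, monotone Kratky curves,
zero reference means and zero-spread calibrations all raise typed errors.
Recovery suites use 20 seeds per condition and the null-calibration check
200 simulated studies on the default 400-point SAXS grid — sizes chosen so
the whole suite completes in seconds while medians are stable. Study runs
are pure functions of (config, seed): re-running byte-reproduces every
table.

## Known limitations

* The Scherrer relation with shape factor 1 and no instrument broadening
  systematically interprets peak width as crystal size only up to a
  constant; comparisons between conditions are unaffected.
* The crystallinity index depends on the fit window and on the
  observed-total convention; absolute values are not comparable across
  conventions, only within a study.
* With triplicates, the Welch test is slightly conservative (measured
  type-I rate ≈ 0.04 at nominal 0.05 under the default null simulation).
* Per-measure t-tests are uncorrected, so a study reporting ~10 WAXS-side
  measures will occasionally flag one by chance; the primary endpoint of a
  spacing study is the single d_cc comparison.
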