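# cellscatter

X-ray scattering analysis of cellulose microfibril structure, for people who
study fibrillation of cellulosic materials — e.g. the action of microbial
expansins or other non-lytic proteins on kraft pulp. The package reduces
wide- and small-angle scattering (WAXS/SAXS) measurements to the handful of
numbers such studies compare between treatments:

* **WAXS** — the 0.7–2.0 Å⁻¹ region is decomposed into four crystalline
  cellulose Iβ Gaussians (the 1-10, 110, 102 and 200 reflections) on one
  broad amorphous Gaussian. Each peak position *q*ₘₐₓ gives a lattice
  d-spacing by Bragg's law, *d* = 2π/*q*ₘₐₓ; each width Δ*q* gives a crystal
  size by the Scherrer relation, *L* = 2π/Δ*q* (shape factor 1); and the
  crystallinity index is the summed crystalline peak area over the total
  area under the intensity curve in the fit window.
* **SAXS** — after subtracting an *A·q*⁻ᵅ power law fitted at low *q*
  (α = 4 for dry samples) and a constant fitted at high *q*, the Kratky
  plot *q*²·*I*(*q*) vs *q* shows the fibril-packing peak. A Gaussian fit
  locates *q*_peak, and *d*_cc = 2π/*q*_peak is the average center-to-center
  distance between microfibrils (≈ 3–5 nm diameter fibrils, spacings of a
  few nm). A peak shift to lower *q* means wider spacing.
* **Statistics** — triplicate aggregation (mean, *n*−1 sd), percent change
  versus a reference condition and two-tailed t-tests (Welch by default,
  significance at *p* ≤ 0.05), plus two small assay formulas: pull-down
  percent-bound, (1 − final/initial)·100, and linear standard-curve
  quantification for reducing-sugar assays.
* **Reduction** — profile text I/O, azimuthal integration of 2D pinhole
  detector images (*q* = (4π/λ)sin θ per pixel), exposure/flux
  normalization, empty-holder background subtraction, replicate averaging.
* **Simulation** — forward generators for WAXS/SAXS profiles, isotropic
  detector images and full reference-vs-treated studies with known ground
  truth, used throughout the test suite for parameter-recovery checks.

## Worked example

`examples/02_saxs_fibril_spacing.py` simulates a SAXS measurement with a
true 40 Å fibril spacing and 1% noise, then runs the full reduction:

```
background: A = 0.001998 (q^-4), c = 0.5015
Kratky peak: q_peak = 0.15705 1/A, fwhm = 0.05989 1/A
center-to-center distance: 40.01 A = 4.001 nm (truth 40.0 A)
```

The fitted background matches the generating values (A = 0.002, c = 0.5),
and the Kratky peak at 0.157 Å⁻¹ converts to a 40.0 Å center-to-center
distance — the estimator recovers the truth to 0.03% at this noise level.

`examples/03_treatment_study.py` runs a triplicate study in which the
treatment widens the true spacing by 22% without touching the crystals:

```
reference  d_cc = 39.79 +/- 0.56 A (n = 3.0)
treated    d_cc = 49.05 +/- 0.30 A (n = 3.0)

spacing change: +23.3% (p = 0.00013, two-tailed t-test)*
crystallinity index change: -0.2% (p = 0.39)
```

The spacing change is recovered and significant while the WAXS-side
crystallinity is not — the pattern expected of a fibril-loosening
treatment. The other examples cover the WAXS decomposition
(`01_waxs_crystallinity.py`) and 2D-image integration
(`04_detector_integration.py`).

A thin CLI mirrors the library (`cellscatter simulate | integrate |
waxs-fit | saxs-fit | compare | run`); run `cellscatter --help`.

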