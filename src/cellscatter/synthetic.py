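"""Forward simulation of WAXS/SAXS measurements with known ground truth.

No public scattering data exist for the pulp system this package analyses,
so parameter-recovery testing runs on simulated measurements built from
the same model families the analysis assumes:

* WAXS: four crystalline cellulose Iβ Gaussians (1-10, 110, 102, 200) on
  one broad amorphous Gaussian, on a grid inside the wide-angle coverage
  0.1–3.0 Å⁻¹;
* SAXS: ``A·q⁻⁴`` power law + constant + a fibril-packing peak that is
  Gaussian **in Kratky space** (so its Kratky transform is exactly
  Gaussian), on a grid inside the small-angle coverage 0.01–0.3 Å⁻¹;
* noise: multiplicative Gaussian with a fractional amplitude (default 1%),
  optional Poisson counting noise for detector images;
* studies: ≥3 replicates per condition; the treated condition's packing
  peak is shifted to lower q by the built-in spacing increase.

Every generator is a pure function of (truth, seed); each artifact carries
its ground truth alongside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .detector import DetectorGeometry, DetectorImage, pixel_q_map
from .errors import ValidationError
from .profiles import ScatteringProfile
from .saxs import center_to_center_distance
from .waxs import (
    CRYSTALLINE_LABELS,
    AMORPHOUS_LABEL,
    DEFAULT_WAXS_INIT,
    DEFAULT_WAXS_WINDOW,
    FWHM_TO_SIGMA,
    gaussian,
    gaussian_area,
)

__all__ = [
    "SyntheticTruth",
    "TreatmentStudy",
    "default_waxs_truth",
    "default_saxs_truth",
    "waxs_truth_ci",
    "generate_waxs_profile",
    "generate_saxs_profile",
    "generate_detector_image",
    "generate_treatment_study",
]

WAXS_COVERAGE = (0.1, 3.0)  # Å⁻¹
SAXS_COVERAGE = (0.01, 0.3)  # Å⁻¹


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated measurement.

    ``waxs_peaks`` maps label → (center, fwhm, amplitude); ``saxs_background``
    is (A, α, c) and ``saxs_peak`` the Kratky-space Gaussian
    (q_peak, fwhm, amplitude). ``noise_fraction`` is the multiplicative
    Gaussian noise level (0 = noiseless).
    """

    modality: str
    q_grid: tuple[float, float, int]
    waxs_peaks: dict[str, tuple[float, float, float]] | None = None
    saxs_background: tuple[float, float, float] | None = None
    saxs_peak: tuple[float, float, float] | None = None
    noise_fraction: float = 0.01

    def __post_init__(self) -> None:
        lo, hi, n = self.q_grid
        if not (0 < lo < hi) or n < 8:
            raise ValidationError("q_grid must be (low, high, n>=8) with 0 < low < high")
        if self.noise_fraction < 0:
            raise ValidationError("noise_fraction must be >= 0")
        cov = WAXS_COVERAGE if self.modality == "WAXS" else SAXS_COVERAGE
        if lo < cov[0] - 1e-12 or hi > cov[1] + 1e-12:
            raise ValidationError(f"{self.modality} grid must lie within coverage {cov}")
        if self.modality == "WAXS":
            if self.waxs_peaks is None:
                raise ValidationError("WAXS truth needs waxs_peaks")
            for label, (c, w, a) in self.waxs_peaks.items():
                if not (lo <= c <= hi):
                    raise ValidationError(f"peak {label} center {c} outside the q grid")
                if w <= 0 or a < 0:
                    raise ValidationError(f"peak {label} has invalid fwhm/amplitude")
        elif self.modality == "SAXS":
            if self.saxs_background is None or self.saxs_peak is None:
                raise ValidationError("SAXS truth needs saxs_background and saxs_peak")
            qp = self.saxs_peak[0]
            if not (lo <= qp <= hi):
                raise ValidationError(f"saxs q_peak {qp} outside the q grid")
        else:
            raise ValidationError(f"unknown modality {self.modality!r}")

    def q(self) -> np.ndarray:
        lo, hi, n = self.q_grid
        return np.linspace(lo, hi, n)

    @property
    def d_cc(self) -> float:
        """True center-to-center distance (SAXS truth only), Å."""
        if self.saxs_peak is None:
            raise ValidationError("d_cc is defined only for SAXS truths")
        return center_to_center_distance(self.saxs_peak[0])

    def replace(self, **changes) -> "SyntheticTruth":
        return dataclasses.replace(self, **changes)


def _gauss_area_window(center, fwhm, amplitude, lo, hi) -> float:
    """Analytic Gaussian area restricted to [lo, hi]."""
    sigma = fwhm * FWHM_TO_SIGMA
    full = gaussian_area(amplitude, fwhm)
    frac = 0.5 * (erf((hi - center) / (sigma * np.sqrt(2))) - erf((lo - center) / (sigma * np.sqrt(2))))
    return full * frac


def waxs_truth_ci(truth: SyntheticTruth, window: tuple[float, float] = DEFAULT_WAXS_WINDOW) -> float:
    """Analytic crystallinity index implied by a WAXS truth.

    Numerator: full crystalline Gaussian areas (as in the analysis);
    denominator: total model intensity integrated over the fit window.
    """
    peaks = truth.waxs_peaks
    num = sum(gaussian_area(peaks[l][2], peaks[l][1]) for l in CRYSTALLINE_LABELS)
    den = sum(_gauss_area_window(c, w, a, *window) for (c, w, a) in peaks.values())
    return num / den


def default_waxs_truth(
    ci: float = 0.55,
    noise_fraction: float = 0.01,
    q_grid: tuple[float, float, int] = (0.1, 3.0, 800),
) -> SyntheticTruth:
    """WAXS fixture truth: standard Iβ peak positions, target crystallinity.

    The amorphous amplitude is solved in closed form so that the analytic
    crystallinity index over the default fit window equals ``ci``.
    """
    if not (0 < ci < 1):
        raise ValidationError("ci must lie in (0, 1)")
    peaks = {
        "1-10": (1.05, 0.10, 0.60),
        "110": (1.17, 0.10, 0.90),
        "102": (1.46, 0.12, 0.40),
        "200": (1.60, 0.09, 1.00),
    }
    lo, hi = DEFAULT_WAXS_WINDOW
    num = sum(gaussian_area(a, w) for (_, w, a) in peaks.values())
    cry_win = sum(_gauss_area_window(c, w, a, lo, hi) for (c, w, a) in peaks.values())
    am_c, am_w = DEFAULT_WAXS_INIT[AMORPHOUS_LABEL]["center"], DEFAULT_WAXS_INIT[AMORPHOUS_LABEL]["fwhm"]
    am_unit = _gauss_area_window(am_c, am_w, 1.0, lo, hi)
    am_amp = (num / ci - cry_win) / am_unit
    if am_amp < 0:
        raise ValidationError(f"target ci {ci} not reachable with the default peak set")
    full = dict(peaks)
    full[AMORPHOUS_LABEL] = (am_c, am_w, float(am_amp))
    return SyntheticTruth(
        modality="WAXS", q_grid=q_grid, waxs_peaks=full, noise_fraction=noise_fraction
    )


def default_saxs_truth(
    d_cc: float = 40.0,
    noise_fraction: float = 0.01,
    q_grid: tuple[float, float, int] = (0.01, 0.3, 400),
) -> SyntheticTruth:
    """SAXS fixture truth: 40 Å fibril spacing, q⁻⁴ + constant background."""
    q_peak = 2.0 * np.pi / d_cc
    return SyntheticTruth(
        modality="SAXS",
        q_grid=q_grid,
        saxs_background=(2.0e-3, 4.0, 0.5),
        saxs_peak=(float(q_peak), 0.06, 1.0),
        noise_fraction=noise_fraction,
    )


def _apply_noise(intensity: np.ndarray, truth: SyntheticTruth, rng: np.random.Generator):
    if truth.noise_fraction == 0:
        return intensity.copy(), None
    noisy = intensity * (1.0 + truth.noise_fraction * rng.standard_normal(intensity.size))
    sigma = truth.noise_fraction * np.abs(intensity)
    return noisy, sigma


def waxs_model(truth: SyntheticTruth, q: np.ndarray) -> np.ndarray:
    """Noiseless five-Gaussian WAXS model of a truth."""
    return np.sum(
        [gaussian(q, a, c, w) for (c, w, a) in truth.waxs_peaks.values()], axis=0
    )


def saxs_model(truth: SyntheticTruth, q: np.ndarray) -> np.ndarray:
    """Noiseless SAXS model: A·q⁻α + c + G_kratky(q)/q²."""
    A, alpha, const = truth.saxs_background
    qp, fwhm, amp = truth.saxs_peak
    return A * q ** (-alpha) + const + gaussian(q, amp, qp, fwhm) / q**2


def generate_waxs_profile(
    truth: SyntheticTruth, seed: int | None = 0
) -> tuple[ScatteringProfile, SyntheticTruth]:
    """Simulate one WAXS measurement; deterministic per (truth, seed)."""
    if truth.modality != "WAXS":
        raise ValidationError("truth modality must be WAXS")
    rng = np.random.default_rng(seed)
    q = truth.q()
    clean = waxs_model(truth, q)
    noisy, sigma = _apply_noise(clean, truth, rng)
    prof = ScatteringProfile(q=q, intensity=noisy, sigma=sigma, modality="WAXS", normalized=True)
    return prof, truth


def generate_saxs_profile(
    truth: SyntheticTruth, seed: int | None = 0
) -> tuple[ScatteringProfile, SyntheticTruth]:
    """Simulate one SAXS measurement; deterministic per (truth, seed)."""
    if truth.modality != "SAXS":
        raise ValidationError("truth modality must be SAXS")
    rng = np.random.default_rng(seed)
    q = truth.q()
    clean = saxs_model(truth, q)
    noisy, sigma = _apply_noise(clean, truth, rng)
    prof = ScatteringProfile(q=q, intensity=noisy, sigma=sigma, modality="SAXS", normalized=True)
    return prof, truth


def generate_detector_image(
    profile: ScatteringProfile,
    geometry: DetectorGeometry,
    shape: tuple[int, int] = (128, 128),
    seed: int | None = 0,
    poisson: bool = False,
) -> DetectorImage:
    """Render an isotropic detector image from a 1D profile.

    Each pixel's q follows from the geometry (same formula the integrator
    uses); its intensity is linearly interpolated from the profile and
    multiplied by exposure × flux_factor to give expected counts. With
    ``poisson=True`` the counts are Poisson-sampled (seeded). Pixels whose
    q falls outside the profile's coverage are masked; if fewer than half
    the pixels are covered the profile is rejected.
    """
    qmap = pixel_q_map(shape, geometry)
    covered = (qmap >= profile.q[0]) & (qmap <= profile.q[-1])
    if covered.mean() < 0.5:
        raise ValidationError(
            f"profile q range {profile.q_range} covers only "
            f"{covered.mean():.0%} of the detector (need >= 50%)"
        )
    factor = geometry.exposure * geometry.flux_factor
    expected = np.where(covered, np.interp(qmap, profile.q, profile.intensity), 0.0) * factor
    expected = np.clip(expected, 0.0, None)
    if poisson:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DetectorImage(
        counts=counts,
        geometry=geometry,
        mask=~covered,
        normalized=False,
        diagnostics={"poisson": poisson, "seed": seed},
    )


@dataclass
class TreatmentStudy:
    """Simulated reference-vs-treated study with its ground truth."""

    saxs_profiles: dict[str, list[ScatteringProfile]]
    waxs_profiles: dict[str, list[ScatteringProfile]]
    truth_table: pd.DataFrame  # tidy: condition, replicate, quantity, value
    seed: int
    spacing_increase: float

    @property
    def conditions(self) -> list[str]:
        return list(self.saxs_profiles)


def generate_treatment_study(
    base_truth: SyntheticTruth | None = None,
    spacing_increase: float = 0.22,
    n_replicates: int = 3,
    replicate_jitter: float = 0.01,
    seed: int = 0,
    waxs_truth: SyntheticTruth | None = None,
) -> TreatmentStudy:
    """Simulate a two-condition study (reference vs treated).

    The treated condition's packing peak is shifted to lower q by dividing
    q_peak by (1 + spacing_increase) — i.e. the true center-to-center
    distance grows by exactly that fraction. Per-replicate truths are
    jittered multiplicatively: the SAXS q_peak by ``replicate_jitter``
    (sample-to-sample packing variation), WAXS amplitudes by
    ``replicate_jitter`` and WAXS centers/widths by a tenth of it. The
    treatment never touches the WAXS truth (spacing-only effect).
    """
    if n_replicates < 3:
        raise ValidationError("need at least 3 parallel replicates per condition")
    if not (0 <= replicate_jitter < 0.2):
        raise ValidationError("replicate_jitter must lie in [0, 0.2)")
    if spacing_increase <= -1:
        raise ValidationError("spacing_increase must be > -1")
    base = base_truth or default_saxs_truth()
    wbase = waxs_truth or default_waxs_truth(noise_fraction=base.noise_fraction)
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(8 * n_replicates + 16, dtype=np.uint32).tolist())

    saxs: dict[str, list[ScatteringProfile]] = {}
    waxs: dict[str, list[ScatteringProfile]] = {}
    rows = []
    for condition, factor in (("reference", 1.0), ("treated", 1.0 + spacing_increase)):
        saxs[condition] = []
        waxs[condition] = []
        for rep in range(1, n_replicates + 1):
            jit_rng = np.random.default_rng(next(child))
            qp, pf, pa = base.saxs_peak
            qp_rep = (qp / factor) * (1.0 + replicate_jitter * jit_rng.standard_normal())
            truth_rep = base.replace(saxs_peak=(float(qp_rep), pf, pa))
            prof, _ = generate_saxs_profile(truth_rep, seed=next(child))
            prof = dataclasses.replace(
                prof, condition=condition, replicate=rep, sample_id=f"{condition}-{rep}"
            )
            saxs[condition].append(prof)
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "quantity": "d_cc_truth_A",
                    "value": truth_rep.d_cc,
                }
            )

            # One draw per family: sample-to-sample variation shifts the whole
            # diffraction pattern coherently (centers together, widths together),
            # while amplitudes vary per reflection.
            wjit = np.random.default_rng(next(child))
            zc = 1.0 + 0.1 * replicate_jitter * wjit.standard_normal()
            zw = 1.0 + 0.1 * replicate_jitter * wjit.standard_normal()
            peaks = {}
            for label, (c, w, a) in wbase.waxs_peaks.items():
                peaks[label] = (
                    float(c * zc),
                    float(w * zw),
                    float(a * (1.0 + replicate_jitter * wjit.standard_normal())),
                )
            wtruth_rep = wbase.replace(waxs_peaks=peaks)
            wprof, _ = generate_waxs_profile(wtruth_rep, seed=next(child))
            wprof = dataclasses.replace(
                wprof, condition=condition, replicate=rep, sample_id=f"{condition}-{rep}"
            )
            waxs[condition].append(wprof)
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "quantity": "ci_truth",
                    "value": waxs_truth_ci(wtruth_rep),
                }
            )
    return TreatmentStudy(
        saxs_profiles=saxs,
        waxs_profiles=waxs,
        truth_table=pd.DataFrame(rows),
        seed=seed,
        spacing_increase=spacing_increase,
    )
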