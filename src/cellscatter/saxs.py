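"""SAXS analysis of cellulose microfibril packing.

The small-angle branch reduces a pulp SAXS profile to a single number, the
average center-to-center distance between microfibrils:

1. fit and subtract the background — a ``q^-α`` power law at low q
   (α = 4 for dry samples) plus a constant fitted at high q;
2. form the Kratky plot, ``q²·I(q)`` vs ``q``, which turns the fibril
   packing correlation into a clear peak;
3. fit a Gaussian to the Kratky peak;
4. convert the peak position with Bragg's law, ``d_cc = 2π/q_peak``.

An upward shift of d_cc (Kratky peak moving to lower q) is the signature
of increased interfibrillar spacing, e.g. after expansin treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .errors import DomainError, NoPeakError, FitError, ValidationError
from .profiles import ScatteringProfile
from .waxs import gaussian

__all__ = [
    "SAXSBackgroundModel",
    "KratkyPeak",
    "SAXSResult",
    "SAXSConfig",
    "fit_saxs_background",
    "subtract_background",
    "kratky_transform",
    "fit_kratky_peak",
    "center_to_center_distance",
    "analyze_saxs",
]

DEFAULT_LOW_Q_WINDOW = (0.010, 0.030)  # Å⁻¹, power-law fit
DEFAULT_HIGH_Q_WINDOW = (0.25, 0.30)  # Å⁻¹, constant fit
DEFAULT_PEAK_WINDOW = (0.05, 0.25)  # Å⁻¹, Kratky peak search


@dataclass
class SAXSBackgroundModel:
    """Power-law + constant background: I_bg(q) = A·q^-α + c."""

    prefactor: float  # A
    exponent: float  # α (4 for dry samples)
    constant: float  # c
    low_q_window: tuple[float, float] = DEFAULT_LOW_Q_WINDOW
    high_q_window: tuple[float, float] = DEFAULT_HIGH_Q_WINDOW

    def __post_init__(self) -> None:
        if self.prefactor < 0 or self.constant < 0:
            # negative fitted values indicate a mis-specified window
            raise ValidationError("background prefactor and constant must be >= 0")
        if not (self.low_q_window[0] < self.low_q_window[1] <= self.high_q_window[0] < self.high_q_window[1]):
            raise ValidationError("windows must be ordered and disjoint (low below high)")

    def evaluate(self, q: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(q, float) ** (-self.exponent) + self.constant


@dataclass
class KratkyPeak:
    """Gaussian fitted to the Kratky plot, q²I vs q."""

    center: float  # q_peak, Å⁻¹
    fwhm: float  # Å⁻¹
    amplitude: float  # Kratky units, intensity·Å⁻²
    ambiguous: bool = False  # multiple equal maxima before the fit
    at_window_edge: bool = False

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValidationError("Kratky peak center must be > 0")
        if self.fwhm <= 0:
            raise ValidationError("Kratky peak fwhm must be > 0")

    @property
    def d_cc(self) -> float:
        """Center-to-center microfibril distance, Å."""
        return center_to_center_distance(self.center)

    @property
    def d_cc_nm(self) -> float:
        return self.d_cc / 10.0


@dataclass
class SAXSResult:
    """Full outcome of the SAXS reduction, intermediates included."""

    background: SAXSBackgroundModel
    peak: KratkyPeak
    subtracted: ScatteringProfile
    kratky: ScatteringProfile
    diagnostics: dict = field(default_factory=dict)

    @property
    def d_cc(self) -> float:
        return self.peak.d_cc

    @property
    def d_cc_nm(self) -> float:
        return self.peak.d_cc_nm


@dataclass(frozen=True)
class SAXSConfig:
    """Tunable windows and background options for :func:`analyze_saxs`."""

    alpha: float | str = 4.0  # fixed exponent, or "free" (wet samples)
    low_q_window: tuple[float, float] = DEFAULT_LOW_Q_WINDOW
    high_q_window: tuple[float, float] = DEFAULT_HIGH_Q_WINDOW
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW


def center_to_center_distance(q_peak: float) -> float:
    """Bragg conversion of the Kratky peak position: d_cc = 2π/q_peak (Å)."""
    if q_peak <= 0:
        raise DomainError(f"q_peak must be > 0, got {q_peak}")
    return 2.0 * math.pi / q_peak


def _window_mask(q: np.ndarray, window: tuple[float, float], what: str, min_points: int = 5):
    m = (q >= window[0]) & (q <= window[1])
    if m.sum() < min_points:
        raise ValidationError(f"{what} window {window} contains {int(m.sum())} points (< {min_points})")
    return m


def fit_saxs_background(
    profile: ScatteringProfile,
    alpha: float | str = 4.0,
    low_q_window: tuple[float, float] = DEFAULT_LOW_Q_WINDOW,
    high_q_window: tuple[float, float] = DEFAULT_HIGH_Q_WINDOW,
) -> SAXSBackgroundModel:
    """Fit the q^-α power law at low q and the flat background at high q.

    With ``alpha`` numeric (default 4, dry samples) the prefactor A is the
    least-squares solution on the low-q window; with ``alpha="free"`` both
    A and α come from a log–log line fit. The constant c is the median of
    the power-law-subtracted intensity over the high-q window (median
    rather than mean for robustness to residual peak tails); A is then
    refined once with c removed.
    """
    if profile.modality != "SAXS":
        raise ValidationError(f"expected a SAXS profile, got modality {profile.modality!r}")
    if high_q_window[0] < low_q_window[1]:
        raise ValidationError("low-q and high-q windows must not overlap")
    q = profile.q
    y = profile.intensity
    mlo = _window_mask(q, low_q_window, "low-q")
    mhi = _window_mask(q, high_q_window, "high-q")

    qlo, ylo = q[mlo], y[mlo]
    if alpha == "free":
        if np.any(ylo <= 0):
            raise FitError("free-α fit requires positive intensities on the low-q window")
        slope, intercept = np.polyfit(np.log(qlo), np.log(ylo), 1)
        a_exp = -float(slope)
        A = float(np.exp(intercept))
    else:
        a_exp = float(alpha)
        basis = qlo ** (-a_exp)
        A = float(basis @ ylo / (basis @ basis))
    c = float(np.median(y[mhi] - A * q[mhi] ** (-a_exp)))
    c = max(c, 0.0)
    # one refinement pass with the constant removed
    basis = qlo ** (-a_exp)
    A = float(basis @ (ylo - c) / (basis @ basis))
    A = max(A, 0.0)
    return SAXSBackgroundModel(
        prefactor=A,
        exponent=a_exp,
        constant=c,
        low_q_window=low_q_window,
        high_q_window=high_q_window,
    )


def subtract_background(
    profile: ScatteringProfile, model: SAXSBackgroundModel
) -> ScatteringProfile:
    """I(q) − A·q^-α − c. Negatives are retained; their fraction is recorded."""
    resid = profile.intensity - model.evaluate(profile.q)
    out = replace(profile, intensity=resid, diagnostics=dict(profile.diagnostics))
    out.diagnostics["frac_negative_after_subtraction"] = float((resid < 0).mean())
    return out


def kratky_transform(profile: ScatteringProfile) -> ScatteringProfile:
    """Kratky plot: pointwise q²·I (uncertainties scaled by q² as well)."""
    q2 = profile.q**2
    return replace(
        profile,
        intensity=profile.intensity * q2,
        sigma=None if profile.sigma is None else profile.sigma * q2,
        diagnostics=dict(profile.diagnostics),
    )


def _smooth5(y: np.ndarray) -> np.ndarray:
    """5-point moving average with shrinking windows at the edges."""
    kernel = np.ones(5)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def fit_kratky_peak(
    kratky: ScatteringProfile,
    init: float | None = None,
    window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
) -> KratkyPeak:
    """Locate and fit the fibril-packing peak of a Kratky curve.

    Initialization: the global argmax of a 5-point moving-average smoothed
    curve over ``window`` (smoothing is used only here, never in the fit);
    ``init`` overrides the center guess. When several smoothed maxima tie,
    the lowest-q one is taken and the result flagged ``ambiguous``. The
    Gaussian is then fitted locally over center ± max(2×fwhm_guess,
    0.05 Å⁻¹). A curve with no interior maximum raises
    :class:`NoPeakError`; a fitted center touching the local window edge
    sets ``at_window_edge``.
    """
    m = _window_mask(kratky.q, window, "peak-analysis", min_points=8)
    q = kratky.q[m]
    y = kratky.intensity[m]
    smooth = _smooth5(y)
    interior = slice(1, -1)
    if init is not None:
        center0 = float(init)
        if not (q[0] < center0 < q[-1]):
            raise ValidationError(f"init center {center0} outside analysis window {window}")
        ambiguous = False
    else:
        smax = smooth[interior].max()
        tie = np.flatnonzero(np.isclose(smooth[interior], smax, rtol=1e-12, atol=0.0)) + 1
        imax = int(tie[0])
        ambiguous = tie.size > 1
        if imax <= 0 or imax >= q.size - 1 or smax <= smooth[0] or smax <= smooth[-1]:
            raise NoPeakError("Kratky curve has no interior maximum in the analysis window")
        center0 = float(q[imax])

    # FWHM guess from the half-maximum crossings of the smoothed curve
    half = smooth.max() / 2.0
    above = smooth >= half
    if above.any():
        lo_i, hi_i = np.flatnonzero(above)[[0, -1]]
        fwhm0 = max(float(q[hi_i] - q[lo_i]), float(np.diff(q).mean()) * 3)
    else:  # pragma: no cover - smoothed max is always >= half of itself
        fwhm0 = 0.05
    halfwidth = max(2.0 * fwhm0, 0.05)
    fit_m = (q >= center0 - halfwidth) & (q <= center0 + halfwidth)
    qf, yf = q[fit_m], y[fit_m]
    if qf.size < 5:
        raise NoPeakError("too few points around the candidate Kratky peak")

    params = lmfit.Parameters()
    params.add("amp", value=max(float(y[np.argmin(np.abs(q - center0))]), 1e-12), min=0.0)
    params.add("center", value=center0, min=float(qf[0]), max=float(qf[-1]))
    params.add("fwhm", value=fwhm0, min=float(np.diff(qf).min()), max=float(qf[-1] - qf[0]) * 2)

    def residual(p):
        return gaussian(qf, p["amp"].value, p["center"].value, p["fwhm"].value) - yf

    fit = lmfit.minimize(residual, params, method="leastsq", max_nfev=10000)
    if not fit.success:
        raise FitError(f"Kratky peak fit failed: {fit.message}")
    center = float(fit.params["center"].value)
    edge = bool(
        np.isclose(center, qf[0], rtol=0, atol=1e-9) or np.isclose(center, qf[-1], rtol=0, atol=1e-9)
    )
    return KratkyPeak(
        center=center,
        fwhm=float(fit.params["fwhm"].value),
        amplitude=float(fit.params["amp"].value),
        ambiguous=ambiguous,
        at_window_edge=edge,
    )


def analyze_saxs(profile: ScatteringProfile, config: SAXSConfig | None = None) -> SAXSResult:
    """Full SAXS reduction: background → subtraction → Kratky → peak → d_cc.

    All intermediates (background model, subtracted profile, Kratky curve)
    are retained on the result for inspection; stage failures are re-raised
    with the stage name prepended.
    """
    cfg = config or SAXSConfig()
    try:
        bg = fit_saxs_background(
            profile, alpha=cfg.alpha, low_q_window=cfg.low_q_window, high_q_window=cfg.high_q_window
        )
    except Exception as exc:
        raise type(exc)(f"[background] {exc}") from exc
    sub = subtract_background(profile, bg)
    kratky = kratky_transform(sub)
    try:
        peak = fit_kratky_peak(kratky, window=cfg.peak_window)
    except Exception as exc:
        raise type(exc)(f"[kratky-peak] {exc}") from exc
    model_resid = sub.intensity * sub.q**2 - gaussian(sub.q, peak.amplitude, peak.center, peak.fwhm)
    return SAXSResult(
        background=bg,
        peak=peak,
        subtracted=sub,
        kratky=kratky,
        diagnostics={
            "kratky_residual_rms": float(np.sqrt(np.mean(model_resid**2))),
            "frac_negative_after_subtraction": sub.diagnostics["frac_negative_after_subtraction"],
        },
    )
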