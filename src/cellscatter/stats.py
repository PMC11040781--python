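"""Replicate statistics and small assay formulas.

Covers the statistical layer of a treatment-comparison scattering study —
triplicate aggregation, percent change against a reference condition and
two-tailed t-tests at p ≤ 0.05 — plus two wet-lab formulas: the
insoluble-polysaccharide pull-down (IPP) percent-bound and linear
standard-curve quantification for colorimetric sugar assays (PAHBAH).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "ConditionSummary",
    "StudyComparison",
    "StandardCurve",
    "SIGNIFICANCE_LEVEL",
    "aggregate_replicates",
    "percent_change",
    "two_tailed_t_test",
    "compare_conditions",
    "percent_bound",
    "fit_standard_curve",
    "quantify",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ConditionSummary:
    """Mean ± sd of one measured quantity across parallel replicates."""

    condition: str
    n: int
    mean: float
    sd: float | None  # None when undefined (n = 1)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("replicate count must be >= 1")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass
class StudyComparison:
    """One treated condition against the reference."""

    reference: ConditionSummary
    treated: ConditionSummary
    percent_change: float
    t_statistic: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value must lie in [0, 1]")
        if self.significant != (self.p_value <= SIGNIFICANCE_LEVEL):
            raise ValidationError("significant flag inconsistent with p-value")


def aggregate_replicates(values: Sequence[float], condition: str = "") -> ConditionSummary:
    """Mean and sample standard deviation (n−1) of replicate measurements.

    With a single replicate the sd is undefined and reported as None.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValidationError("values must be a non-empty 1D sequence")
    if arr.size < 2:
        return ConditionSummary(condition=condition, n=1, mean=float(arr[0]), sd=None)
    return ConditionSummary(
        condition=condition,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
    )


def percent_change(reference: ConditionSummary, treated: ConditionSummary) -> float:
    """Signed percent change of the treated mean vs the reference mean."""
    if reference.mean == 0:
        raise DomainError("reference mean is zero; percent change undefined")
    return 100.0 * (treated.mean - reference.mean) / reference.mean


def two_tailed_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sample two-tailed t-test.

    ``variant="welch"`` (default) does not assume equal variances;
    ``"student"`` is the classical equal-variance test. Degenerate input
    with zero variance in both groups and equal means returns (0, 1) by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in ("welch", "student"):
        raise ValidationError("variant must be 'welch' or 'student'")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def compare_conditions(
    reference_values: Sequence[float],
    treated_values: Sequence[float],
    reference_label: str = "reference",
    treated_label: str = "treated",
    variant: str = "welch",
) -> StudyComparison:
    """Aggregate both conditions and test the treated-vs-reference change."""
    ref = aggregate_replicates(reference_values, reference_label)
    trt = aggregate_replicates(treated_values, treated_label)
    t, p = two_tailed_t_test(treated_values, reference_values, variant=variant)
    return StudyComparison(
        reference=ref,
        treated=trt,
        percent_change=percent_change(ref, trt),
        t_statistic=t,
        p_value=p,
        significant=p <= SIGNIFICANCE_LEVEL,
    )


def percent_bound(initial_conc: float, final_conc: float) -> float:
    """IPP assay: percent of protein bound to the insoluble substrate.

    (1 − final/initial)·100, clamped to [0, 100]. ``final > initial``
    (apparent negative binding) clamps to 0.
    """
    if initial_conc <= 0:
        raise DomainError("initial concentration must be > 0")
    if final_conc < 0:
        raise DomainError("final concentration must be >= 0")
    return float(np.clip((1.0 - final_conc / initial_conc) * 100.0, 0.0, 100.0))


@dataclass
class StandardCurve:
    """Linear map from absorbance to concentration (mg/mL)."""

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]  # concentration domain, mg/mL

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("R² must lie in [0, 1]")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ValidationError("valid_range must be ordered (low, high)")


def fit_standard_curve(
    concentrations: Sequence[float], absorbances: Sequence[float]
) -> StandardCurve:
    """Ordinary least-squares calibration line, absorbance → concentration.

    Needs ≥ 3 calibration points; the glucose standards of the emulated
    assay span 0.01–0.3 mg/mL.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 3:
        raise ValidationError("need >= 3 matched calibration points")
    if np.ptp(a) == 0:
        raise FitError("absorbances are degenerate (no spread); cannot calibrate")
    res = sps.linregress(a, c)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range=(float(c.min()), float(c.max())),
    )


def quantify(absorbance: float, curve: StandardCurve) -> tuple[float, bool]:
    """Concentration (mg/mL) for an absorbance reading.

    Returns ``(concentration, extrapolated)``; ``extrapolated`` is True when
    the result falls outside the curve's calibrated concentration range.
    """
    conc = curve.slope * float(absorbance) + curve.intercept
    lo, hi = curve.valid_range
    extrapolated = not (lo - 1e-12 <= conc <= hi + 1e-12)
    return float(conc), extrapolated
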