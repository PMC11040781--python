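"""1D scattering profiles: container, text I/O, normalization, reduction.

A :class:`ScatteringProfile` is the reduced form of a small- or wide-angle
X-ray scattering (SAXS/WAXS) measurement: scattering-vector magnitudes
``q`` (Å⁻¹), intensities (counts or counts/s, arbitrary scale) and optional
per-point uncertainties. All downstream analysis (crystallinity, fibril
spacing) consumes this type.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParseError, StateError, ValidationError

__all__ = [
    "ScatteringProfile",
    "read_profile",
    "write_profile",
    "subtract_empty_holder",
    "average_profiles",
]

_MODALITIES = ("SAXS", "WAXS")

_META_KEYS = ("modality", "sample_id", "condition", "replicate", "normalized")


@dataclass
class ScatteringProfile:
    """A reduced 1D scattering measurement.

    Parameters
    ----------
    q
        Scattering-vector magnitudes in Å⁻¹, strictly increasing, > 0.
    intensity
        Scattered intensity on an arbitrary scale (counts or counts/s).
    sigma
        Optional per-point uncertainty, same units as ``intensity``.
    modality
        ``"SAXS"`` or ``"WAXS"``.
    sample_id, condition, replicate
        Free-text labels used by the study-comparison layer.
    normalized
        True once intensities are in per-second units
        (see :func:`normalize_exposure` in :mod:`cellscatter.detector`).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    modality: str = "SAXS"
    sample_id: str = ""
    condition: str = ""
    replicate: int = 0
    normalized: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.modality not in _MODALITIES:
            raise ValidationError(f"modality must be one of {_MODALITIES}, got {self.modality!r}")
        if self.q.ndim != 1 or self.q.size < 8:
            raise ValidationError(f"q must be 1D with at least 8 points, got shape {self.q.shape}")
        if self.intensity.shape != self.q.shape:
            raise ValidationError("q and intensity must have identical length")
        if self.sigma is not None:
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma must have the same length as q")
            if np.any(self.sigma < 0):
                raise ValidationError("sigma must be non-negative")
        if np.any(self.q <= 0):
            raise ValidationError("q values must be strictly positive")
        dq = np.diff(self.q)
        if np.any(dq == 0):
            raise ValidationError("duplicate q values are not allowed")
        if np.any(dq < 0):
            raise ValidationError("q must be strictly increasing (use read_profile to sort)")

    def __len__(self) -> int:
        return int(self.q.size)

    @property
    def q_range(self) -> tuple[float, float]:
        return float(self.q[0]), float(self.q[-1])

    def scaled(self, factor: float) -> "ScatteringProfile":
        """Return a copy with intensity (and sigma) multiplied by ``factor``."""
        return replace(
            self,
            intensity=self.intensity * factor,
            sigma=None if self.sigma is None else self.sigma * abs(factor),
            diagnostics=dict(self.diagnostics),
        )

    def restricted(self, lo: float, hi: float) -> "ScatteringProfile":
        """Return the sub-profile with lo <= q <= hi."""
        m = (self.q >= lo) & (self.q <= hi)
        if m.sum() < 8:
            raise ValidationError(f"window [{lo}, {hi}] leaves fewer than 8 points")
        return replace(
            self,
            q=self.q[m],
            intensity=self.intensity[m],
            sigma=None if self.sigma is None else self.sigma[m],
            diagnostics=dict(self.diagnostics),
        )


def _sorted_arrays(q, i, s):
    order = np.argsort(q, kind="stable")
    q = q[order]
    i = i[order]
    s = None if s is None else s[order]
    if np.any(np.diff(q) == 0):
        raise ValidationError("duplicate q values in input")
    return q, i, s


def read_profile(path: str | Path, dialect: Sequence[str] | None = None) -> ScatteringProfile:
    """Read a delimited-text profile (columns ``q I [sigma]``).

    Lines starting with ``#`` are comments; ``# key: value`` comments written
    by :func:`write_profile` restore modality and sample labels. Rows are
    whitespace- or comma-delimited. The returned profile is sorted by
    ascending q; duplicate q values raise :class:`ValidationError`.

    ``dialect`` optionally names the columns in file order (a permutation of
    ``("q", "intensity", "sigma")``); by default the columns are taken as
    q, intensity and, if present, sigma.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    ncols = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key in _META_KEYS:
                        meta[key] = val.strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric row: {line!r}") from exc
            if ncols is None:
                ncols = len(vals)
                if ncols < 2:
                    raise ParseError(f"{path}:{lineno}: need at least 2 columns (q, I)")
            elif len(vals) != ncols:
                raise ParseError(f"{path}:{lineno}: expected {ncols} columns, got {len(vals)}")
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    if dialect is None:
        dialect = ("q", "intensity", "sigma")[: data.shape[1]]
    cols = {name: data[:, k] for k, name in enumerate(dialect)}
    q, inten, sig = _sorted_arrays(cols["q"], cols["intensity"], cols.get("sigma"))
    return ScatteringProfile(
        q=q,
        intensity=inten,
        sigma=sig,
        modality=meta.get("modality", "SAXS"),
        sample_id=meta.get("sample_id", ""),
        condition=meta.get("condition", ""),
        replicate=int(meta.get("replicate", 0) or 0),
        normalized=meta.get("normalized", "false").lower() in ("true", "1", "yes"),
    )


def write_profile(profile: ScatteringProfile, path: str | Path) -> Path:
    """Write a profile as delimited text with a self-describing header.

    Columns are ``q[1/A]``, ``I`` and, if present, ``sigma``; floats are
    written at full precision so a read/write round trip is exact.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# modality: {profile.modality}\n")
    buf.write(f"# sample_id: {profile.sample_id}\n")
    buf.write(f"# condition: {profile.condition}\n")
    buf.write(f"# replicate: {profile.replicate}\n")
    buf.write(f"# normalized: {profile.normalized}\n")
    if profile.sigma is None:
        buf.write("# columns: q[1/A] I[counts/s]\n")
        for qv, iv in zip(profile.q, profile.intensity):
            buf.write(f"{qv:.17g} {iv:.17g}\n")
    else:
        buf.write("# columns: q[1/A] I[counts/s] sigma[counts/s]\n")
        for qv, iv, sv in zip(profile.q, profile.intensity, profile.sigma):
            buf.write(f"{qv:.17g} {iv:.17g} {sv:.17g}\n")
    path.write_text(buf.getvalue())
    return path


def _interp_onto(target_q: np.ndarray, src: ScatteringProfile):
    """Linear interpolation of ``src`` onto ``target_q``; no extrapolation."""
    inside = (target_q >= src.q[0]) & (target_q <= src.q[-1])
    vals = np.interp(target_q[inside], src.q, src.intensity)
    sig = None if src.sigma is None else np.interp(target_q[inside], src.q, src.sigma)
    return inside, vals, sig


def subtract_empty_holder(
    sample: ScatteringProfile,
    empty: ScatteringProfile,
    scale: float = 1.0,
) -> ScatteringProfile:
    """Subtract the empty-sample-holder background from a measurement.

    Both profiles must already be in per-second units. The empty-holder
    profile is linearly interpolated onto the sample grid; the overlap must
    cover at least 90% of the sample's q points. The result is
    ``sample − scale·empty`` with negative values retained (their count is
    recorded under ``diagnostics["n_negative"]``) and uncertainties added
    in quadrature where both are present.
    """
    if not (sample.normalized and empty.normalized):
        raise StateError("both profiles must be normalized to per-second units first")
    inside, bg, bg_sig = _interp_onto(sample.q, empty)
    overlap = inside.mean()
    if overlap < 0.90:
        raise ValidationError(
            f"empty-holder q range covers only {overlap:.0%} of the sample grid (need >= 90%)"
        )
    q = sample.q[inside]
    inten = sample.intensity[inside] - scale * bg
    sig = None
    if sample.sigma is not None and bg_sig is not None:
        sig = np.hypot(sample.sigma[inside], scale * bg_sig)
    elif sample.sigma is not None:
        sig = sample.sigma[inside]
    n_neg = int((inten < 0).sum())
    out = ScatteringProfile(
        q=q,
        intensity=inten,
        sigma=sig,
        modality=sample.modality,
        sample_id=sample.sample_id,
        condition=sample.condition,
        replicate=sample.replicate,
        normalized=True,
    )
    out.diagnostics.update(sample.diagnostics)
    out.diagnostics["n_negative"] = n_neg
    out.diagnostics["frac_negative"] = n_neg / q.size
    out.diagnostics["background_scale"] = scale
    return out


def average_profiles(profiles: Sequence[ScatteringProfile]) -> ScatteringProfile:
    """Pointwise mean of replicate profiles on the first profile's q grid.

    Mirrors the convention of reporting averages of at least three parallel
    samples: sigma of the result is the pointwise sample standard deviation
    (n−1) across replicates. Profiles are linearly interpolated onto the
    first profile's grid restricted to the common q overlap.
    """
    if len(profiles) < 2:
        raise ValidationError("need >= 2 profiles to average; pass the single profile through unchanged")
    modality = profiles[0].modality
    if any(p.modality != modality for p in profiles):
        raise ValidationError("cannot average profiles of mixed modality")
    lo = max(p.q[0] for p in profiles)
    hi = min(p.q[-1] for p in profiles)
    grid = profiles[0].q[(profiles[0].q >= lo) & (profiles[0].q <= hi)]
    if grid.size < 8:
        raise ValidationError("common q overlap of the profiles is too small")
    stack = np.vstack([np.interp(grid, p.q, p.intensity) for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    return ScatteringProfile(
        q=grid,
        intensity=mean,
        sigma=sd,
        modality=modality,
        sample_id=profiles[0].sample_id,
        condition=profiles[0].condition,
        normalized=profiles[0].normalized,
        diagnostics={"n_averaged": len(profiles)},
    )
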