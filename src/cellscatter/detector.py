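"""2D detector images: geometry, azimuthal integration, normalization.

Pinhole (flat-detector, normal-incidence) geometry only. Each pixel's
scattering angle follows from its radial distance to the beam center:
``2θ = arctan(r·pixel_size / distance)`` and ``q = (4π/λ)·sin θ``.

Conventions (fixed, documented):

* pixel centers sit at integer + 0.5 in pixel units; the beam center is
  given in fractional pixel coordinates (row, col); radii are computed
  center-to-center;
* bin aggregation is the plain arithmetic mean of pixel values per
  equal-width q bin — no solid-angle or polarization correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import StateError, ValidationError
from .profiles import ScatteringProfile

__all__ = [
    "DetectorGeometry",
    "DetectorImage",
    "azimuthal_integrate",
    "normalize_exposure",
    "pixel_q_map",
    "read_image_text",
    "write_image_text",
    "read_image_tiff",
    "load_geometry",
    "WAXS_GEOMETRY",
    "SAXS_GEOMETRY",
]

CU_KALPHA_WAVELENGTH_A = 1.542  # Cu Kα, Å


@dataclass(frozen=True)
class DetectorGeometry:
    """Pinhole measurement geometry.

    distance and pixel_size in mm, beam_center in fractional pixel
    coordinates (row, col), wavelength in Å, exposure in s. ``flux_factor``
    is the relative incident beam intensity (1.0 = the WAXS reference beam;
    the SAXS beam of the emulated instrument is 4.5× more intense to
    compensate for its shorter acquisitions).
    """

    distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    wavelength: float = CU_KALPHA_WAVELENGTH_A
    exposure: float = 1.0
    flux_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("distance", "pixel_size", "wavelength", "exposure", "flux_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"geometry field {name} must be > 0")


# Instrument defaults emulating a lab Cu-source SAXS/WAXS setup.
WAXS_GEOMETRY = DetectorGeometry(
    distance=55.0, pixel_size=0.075, beam_center=(0.0, 0.0), exposure=2400.0, flux_factor=1.0
)
SAXS_GEOMETRY = DetectorGeometry(
    distance=600.0, pixel_size=0.075, beam_center=(0.0, 0.0), exposure=1000.0, flux_factor=4.5
)


@dataclass
class DetectorImage:
    """2D counts with an exclusion mask and the geometry that produced them."""

    counts: np.ndarray
    geometry: DetectorGeometry
    mask: np.ndarray | None = None
    normalized: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2D array")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValidationError("mask and counts must have identical shape")


def pixel_q_map(shape: tuple[int, int], geometry: DetectorGeometry) -> np.ndarray:
    """q (Å⁻¹) at each pixel center for the given geometry."""
    rows = np.arange(shape[0])[:, None] + 0.5
    cols = np.arange(shape[1])[None, :] + 0.5
    r_pix = np.hypot(rows - geometry.beam_center[0], cols - geometry.beam_center[1])
    two_theta = np.arctan(r_pix * geometry.pixel_size / geometry.distance)
    return (4.0 * np.pi / geometry.wavelength) * np.sin(two_theta / 2.0)


def normalize_exposure(obj, geometry: DetectorGeometry | None = None):
    """Convert counts to per-second units: divide by exposure × flux_factor.

    Accepts a :class:`DetectorImage` or a :class:`ScatteringProfile` (the
    latter needs ``geometry``). Normalization is recorded on the object and
    a second attempt raises :class:`StateError`.
    """
    if isinstance(obj, DetectorImage):
        if obj.normalized:
            raise StateError("image is already normalized to per-second units")
        geo = obj.geometry
        factor = geo.exposure * geo.flux_factor
        out = DetectorImage(
            counts=obj.counts / factor,
            geometry=geo,
            mask=obj.mask.copy(),
            normalized=True,
            diagnostics=dict(obj.diagnostics),
        )
        out.diagnostics["normalization_factor"] = factor
        return out
    if isinstance(obj, ScatteringProfile):
        if obj.normalized:
            raise StateError("profile is already normalized to per-second units")
        if geometry is None:
            raise ValidationError("profile normalization requires a DetectorGeometry")
        factor = geometry.exposure * geometry.flux_factor
        out = replace(
            obj,
            intensity=obj.intensity / factor,
            sigma=None if obj.sigma is None else obj.sigma / factor,
            normalized=True,
            diagnostics=dict(obj.diagnostics),
        )
        out.diagnostics["normalization_factor"] = factor
        return out
    raise ValidationError(f"cannot normalize object of type {type(obj).__name__}")


def azimuthal_integrate(
    image: DetectorImage,
    n_bins: int,
    q_range: tuple[float, float],
    modality: str = "SAXS",
) -> ScatteringProfile:
    """Azimuthally integrate a 2D image into a 1D I(q) profile.

    Unmasked pixels are assigned to ``n_bins`` equal-width q bins spanning
    ``q_range`` and mean-aggregated; empty bins are dropped. Bin uncertainty
    is √(Σ counts)/n_pixels (Poisson counting), expressed in the same units
    as the image (per-second if the image was normalized first).
    """
    if n_bins < 8:
        raise ValidationError("n_bins must be >= 8")
    qlo, qhi = q_range
    if not qlo < qhi:
        raise ValidationError("q_range must be (low, high) with low < high")
    valid = ~image.mask
    if not valid.any():
        raise ValidationError("all pixels are masked")
    qmap = pixel_q_map(image.counts.shape, image.geometry)
    qcov = qmap[valid]
    if qlo >= qcov.max() or qhi <= qcov.min():
        raise ValidationError(
            f"q_range {q_range} lies outside detector coverage "
            f"[{qcov.min():.4g}, {qcov.max():.4g}]"
        )
    edges = np.linspace(qlo, qhi, n_bins + 1)
    qv = qmap[valid]
    iv = image.counts[valid]
    inside = (qv >= qlo) & (qv < qhi)
    qv, iv = qv[inside], iv[inside]
    idx = np.digitize(qv, edges) - 1
    counts_per_bin = np.bincount(idx, minlength=n_bins)
    sum_per_bin = np.bincount(idx, weights=iv, minlength=n_bins)
    nonempty = counts_per_bin > 0
    if nonempty.sum() < 8:
        raise ValidationError("fewer than 8 non-empty q bins; widen q_range or reduce n_bins")
    centers = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    mean_i = sum_per_bin[nonempty] / counts_per_bin[nonempty]
    # Poisson counting error on the raw-count scale, mapped back to image units.
    geo = image.geometry
    scale = geo.exposure * geo.flux_factor if image.normalized else 1.0
    raw_sum = sum_per_bin[nonempty] * scale
    sigma = np.sqrt(np.clip(raw_sum, 0, None)) / counts_per_bin[nonempty] / scale
    return ScatteringProfile(
        q=centers,
        intensity=mean_i,
        sigma=sigma,
        modality=modality,
        normalized=image.normalized,
        diagnostics={"n_pixels_used": int(counts_per_bin[nonempty].sum())},
    )


def write_image_text(image: DetectorImage, path: str | Path) -> Path:
    """Write the counts grid as whitespace-delimited text (one row per line)."""
    path = Path(path)
    np.savetxt(path, image.counts, fmt="%.17g")
    return path


def read_image_text(path: str | Path, geometry: DetectorGeometry) -> DetectorImage:
    """Read a counts grid written as whitespace-delimited text."""
    counts = np.loadtxt(Path(path))
    return DetectorImage(counts=counts, geometry=geometry)


def read_image_tiff(path: str | Path, geometry: DetectorGeometry) -> DetectorImage:
    """Read a single-frame TIFF as a detector image."""
    import tifffile

    counts = np.asarray(tifffile.imread(str(path)), dtype=float)
    if counts.ndim != 2:
        raise ValidationError("only single-frame 2D TIFFs are supported")
    return DetectorImage(counts=counts, geometry=geometry)


def load_geometry(mapping: dict) -> DetectorGeometry:
    """Build a geometry from config keys.

    Recognized keys: distance_mm, pixel_mm, beam_center (two numbers),
    wavelength_A (default 1.542), exposure_s (default 1), flux_factor
    (default 1). Unknown keys are rejected.
    """
    known = {"distance_mm", "pixel_mm", "beam_center", "wavelength_A", "exposure_s", "flux_factor"}
    unknown = set(mapping) - known
    if unknown:
        raise ValidationError(f"unknown geometry keys: {sorted(unknown)}")
    try:
        bc = tuple(float(x) for x in mapping["beam_center"])
        return DetectorGeometry(
            distance=float(mapping["distance_mm"]),
            pixel_size=float(mapping["pixel_mm"]),
            beam_center=(bc[0], bc[1]),
            wavelength=float(mapping.get("wavelength_A", CU_KALPHA_WAVELENGTH_A)),
            exposure=float(mapping.get("exposure_s", 1.0)),
            flux_factor=float(mapping.get("flux_factor", 1.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"missing geometry key: {exc}") from exc
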