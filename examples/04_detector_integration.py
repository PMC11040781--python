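"""From a 2D detector image to a 1D I(q) profile.

Renders an isotropic detector image from a known smooth curve (pinhole
geometry, 600 mm distance), azimuthally integrates it back, normalizes to
per-second units and reports the agreement with the generating curve.
"""

import numpy as np

from cellscatter import (
    DetectorGeometry,
    ScatteringProfile,
    azimuthal_integrate,
    generate_detector_image,
    normalize_exposure,
)
from cellscatter.detector import pixel_q_map

geometry = DetectorGeometry(
    distance=600.0, pixel_size=0.75, beam_center=(64.0, 64.0), exposure=1000.0, flux_factor=4.5
)
qmap = pixel_q_map((128, 128), geometry)
q_range = (float(qmap.min()) + 1e-6, float(qmap.max()))

q = np.linspace(q_range[0] * 0.5, q_range[1] * 1.05, 500)
curve = ScatteringProfile(q=q, intensity=np.exp(-(q**2)), normalized=True)

image = generate_detector_image(curve, geometry, shape=(128, 128), seed=0, poisson=False)
profile = normalize_exposure(azimuthal_integrate(image, n_bins=50, q_range=q_range), geometry)

# normalization undid the exposure x flux scaling, so the per-second profile
# sits directly on the generating curve's scale
recovered = profile.intensity
truth = np.exp(-(profile.q**2))
rms = np.sqrt(np.mean((recovered[2:-2] / truth[2:-2] - 1.0) ** 2))

print(f"detector q coverage: {q_range[0]:.4f} - {q_range[1]:.4f} 1/A")
print(f"integrated bins: {len(profile)}, round-trip RMS deviation: {100 * rms:.3f}%")
print(
    "\nEach pixel maps to q = (4π/λ)sin(θ) from its radius; mean-aggregating\n"
    "pixels into equal-width q bins recovers the generating 1D curve to well\n"
    "under 1% - the accuracy floor of the reduction step."
)
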