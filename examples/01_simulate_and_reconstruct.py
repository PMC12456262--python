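"""Simulate a CT acquisition of a synthetic patient slice and reconstruct it.

Builds an eccentric (shoulder-like) phantom, forward projects it to a
fan-beam sinogram, and reconstructs with filtered backprojection. The
printed numbers show that the reconstruction recovers the phantom's
attenuation values to within a few HU inside the body.
"""

import numpy as np

from nadd_ct import DESK_GEOMETRY, forward_project, make_phantom, reconstruct
from nadd_ct.phantoms import PhantomSpec

geometry = DESK_GEOMETRY
spec = PhantomSpec(
    body_half_axes=(120.0, 55.0),  # mm; ratio 2.2 -> eccentric, like shoulders
    eccentricity="eccentric",
    n_inserts=3,
    background_hu=40.0,
    seed=7,
)
phantom = make_phantom(spec, geometry)
sinogram = forward_project(phantom, geometry)
recon = reconstruct(sinogram, geometry)

ny, nx = geometry.image_shape()
center = np.s_[ny // 2 - 5 : ny // 2 + 5, nx // 2 - 5 : nx // 2 + 5]
print(f"sinogram shape (views x detectors): {sinogram.shape}")
print(f"max line integral: {sinogram.values.max():.2f} (dimensionless attenuation)")
print(f"phantom center mean: {phantom.pixels[center].mean():7.1f} HU")
print(f"recon   center mean: {recon.pixels[center].mean():7.1f} HU")
print(f"center error: {abs(recon.pixels[center].mean() - phantom.pixels[center].mean()):.1f} HU")
print("-> FBP recovers the soft-tissue value to within a few HU; the residual")
print("   comes from the band-limited ramp filter and interpolation.")
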