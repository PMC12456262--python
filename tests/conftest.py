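import numpy as np
import pytest

from nadd_ct import DESK_GEOMETRY, ImageSlice, ScanGeometry

# tiny geometry for unit tests that only need a consistent chain, not accuracy
MICRO_GEOMETRY = ScanGeometry(
    R_F=650.0,
    R_D=420.0,
    n_views=128,
    n_det=140,
    det_pitch=2.4,
    n_x=64,
    n_y=64,
    pixel_size=2.0,
    n_det_rows=1,
)


@pytest.fixture(scope="session")
def micro_geometry():
    return MICRO_GEOMETRY


@pytest.fixture(scope="session")
def desk_geometry():
    return DESK_GEOMETRY


def disk_image(geometry, radius_mm=50.0, hu=100.0, center=(0.0, 0.0), supersample=4):
    """Anti-aliased uniform disk on the geometry's grid (HU, air outside)."""
    ny, nx = geometry.image_shape()
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ss = supersample
    idx = (np.arange(nx * ss) + 0.5) / ss - 0.5
    idy = (np.arange(ny * ss) + 0.5) / ss - 0.5
    yy, xx = np.meshgrid((cy - idy) * geometry.pixel_size, (idx - cx) * geometry.pixel_size, indexing="ij")
    mask = (np.hypot(xx - center[0], yy - center[1]) <= radius_mm).astype(float)
    cov = mask.reshape(ny, ss, nx, ss).mean(axis=(1, 3))
    return ImageSlice(-1000.0 + cov * (hu + 1000.0), geometry.pixel_size)


def smooth_blob_image(geometry, seed=0, n_blobs=6):
    """Smooth Gaussian-blob phantom (no sharp edges) for round-trip tests."""
    rng = np.random.default_rng(seed)
    ny, nx = geometry.image_shape()
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    yy, xx = np.meshgrid(
        (cy - np.arange(ny)) * geometry.pixel_size,
        (np.arange(nx) - cx) * geometry.pixel_size,
        indexing="ij",
    )
    img = np.full((ny, nx), -1000.0)
    half = 0.45 * min(nx, ny) * geometry.pixel_size
    for _ in range(n_blobs):
        x0, y0 = rng.uniform(-half / 2, half / 2, 2)
        s = rng.uniform(0.1, 0.25) * half
        a = rng.uniform(100, 800)
        img += a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s * s))
    return ImageSlice(np.clip(img, -1000, 3000), geometry.pixel_size)
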