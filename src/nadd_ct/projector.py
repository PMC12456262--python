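"""The X-ray transform and its filtered-backprojection inverse.

This module implements the fan-beam forward projector (Joseph's method: the
line integral is accumulated by stepping along the dominant axis of each ray
with linear interpolation in the transverse direction) and the matching 2D
fan-beam filtered backprojection for a flat detector: cosine pre-weighting,
row-wise ramp filtering on the virtual isocenter detector, and
distance-weighted backprojection. The central detector row of a circular
cone-beam (Feldkamp) reconstruction is exactly this 2D fan-beam FBP, which is
why the package operates on central slices.

Reconstruction is a linear operator; that linearity is what makes noise-only
images (reconstructions of sinogram differences) meaningful.

Units: images are Hounsfield units at the module boundary; internally the
projector integrates the linear attenuation coefficient mu (1/mm), with
``mu = MU_WATER * (1 + HU/1000)`` and ``MU_WATER = 0.0192 / mm`` (a
monochromatic, approximately 70 keV convention — only the ratio of
line integrals matters for the noise model).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .containers import DataError, ImageSlice, Sinogram
from .geometry import ScanGeometry

MU_WATER = 0.0192  # 1/mm


# ---------------------------------------------------------------------------
# HU <-> attenuation
# ---------------------------------------------------------------------------

def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    """Convert Hounsfield units to linear attenuation (1/mm).

    Raises :class:`DataError` for HU below -1000 (air), which would produce
    a negative attenuation coefficient.
    """
    hu = np.asarray(hu, dtype=np.float64)
    if np.any(hu < -1000.0 - 1e-9):
        raise DataError(f"HU values below -1000 (min {hu.min():.2f}) have no attenuation meaning")
    return MU_WATER * (1.0 + hu / 1000.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hu_to_mu`; round-trips to machine precision."""
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / MU_WATER - 1.0)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _joseph_forward(mu, px, n_views, n_det, R_F, R_D, det_pitch, out):
    # mu: (n_y, n_x) attenuation; px: pixel size (mm)
    # image coords: x = (j - cx)*px, y = (cy - i)*px  (row i downward)
    n_y, n_x = mu.shape
    cx = (n_x - 1) / 2.0
    cy = (n_y - 1) / 2.0
    two_pi = 2.0 * np.pi
    for a in range(n_views):
        alpha = two_pi * a / n_views
        ca = np.cos(alpha)
        sa = np.sin(alpha)
        sx = R_F * ca
        sy = R_F * sa
        for k in range(n_det):
            u = (k - (n_det - 1) / 2.0) * det_pitch
            dx_ = -R_D * ca - u * sa
            dy_ = -R_D * sa + u * ca
            rx = dx_ - sx
            ry = dy_ - sy
            acc = 0.0
            if abs(rx) >= abs(ry):
                slope = ry / rx  # dy per dx
                # step through image columns
                step_len = px * np.sqrt(1.0 + slope * slope)
                for j in range(n_x):
                    x = (j - cx) * px
                    y = sy + (x - sx) * slope
                    fi = cy - y / px
                    i0 = int(np.floor(fi))
                    w = fi - i0
                    if 0 <= i0 < n_y - 1:
                        acc += (1.0 - w) * mu[i0, j] + w * mu[i0 + 1, j]
                    elif i0 == -1 and w > 0.0:
                        acc += w * mu[0, j]
                    elif i0 == n_y - 1 and w == 0.0:
                        acc += mu[n_y - 1, j]
                acc *= step_len
            else:
                slope = rx / ry  # dx per dy
                step_len = px * np.sqrt(1.0 + slope * slope)
                for i in range(n_y):
                    y = (cy - i) * px
                    x = sx + (y - sy) * slope
                    fj = x / px + cx
                    j0 = int(np.floor(fj))
                    w = fj - j0
                    if 0 <= j0 < n_x - 1:
                        acc += (1.0 - w) * mu[i, j0] + w * mu[i, j0 + 1]
                    elif j0 == -1 and w > 0.0:
                        acc += w * mu[i, 0]
                    elif j0 == n_x - 1 and w == 0.0:
                        acc += mu[i, n_x - 1]
                acc *= step_len
            out[a, k] = acc


@njit(cache=True)
def _fan_backproject(filtered, px, n_y, n_x, R_F, du_virt, out):
    # filtered: (n_views, n_det) ramp-filtered, cosine-weighted sinogram on
    # the virtual isocenter detector (spacing du_virt)
    n_views, n_det = filtered.shape
    cx = (n_x - 1) / 2.0
    cy = (n_y - 1) / 2.0
    cdet = (n_det - 1) / 2.0
    two_pi = 2.0 * np.pi
    d_alpha = two_pi / n_views
    for a in range(n_views):
        alpha = two_pi * a / n_views
        ca = np.cos(alpha)
        sa = np.sin(alpha)
        row = filtered[a]
        for i in range(n_y):
            y = (cy - i) * px
            for j in range(n_x):
                x = (j - cx) * px
                L = R_F - (x * ca + y * sa)  # distance along source axis
                t = -x * sa + y * ca
                u_virt = R_F * t / L
                fk = u_virt / du_virt + cdet
                k0 = int(np.floor(fk))
                if k0 < 0 or k0 >= n_det - 1:
                    continue
                w = fk - k0
                val = (1.0 - w) * row[k0] + w * row[k0 + 1]
                out[i, j] += val * (R_F * R_F) / (L * L) * d_alpha * 0.5


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _ramp_kernel(n_det: int, spacing: float, filter_name: str) -> np.ndarray:
    """Band-limited spatial-domain ramp kernel, length 2*n_det - 1."""
    n = np.arange(-(n_det - 1), n_det)
    if filter_name == "ram-lak":
        h = np.zeros_like(n, dtype=np.float64)
        h[n == 0] = 1.0 / (4.0 * spacing**2)
        odd = n % 2 == 1
        h[odd] = -1.0 / (np.pi**2 * n[odd] ** 2 * spacing**2)
    elif filter_name == "shepp-logan":
        h = -2.0 / (np.pi**2 * spacing**2 * (4.0 * n.astype(np.float64) ** 2 - 1.0))
    else:
        raise ValueError(f"unknown ramp filter {filter_name!r}; use 'ram-lak' or 'shepp-logan'")
    return h


def _filter_rows(weighted: np.ndarray, spacing: float, filter_name: str) -> np.ndarray:
    n_views, n_det = weighted.shape
    h = _ramp_kernel(n_det, spacing, filter_name)
    n_fft = 1 << int(np.ceil(np.log2(n_det + h.size - 1)))
    H = np.fft.rfft(h, n_fft)
    P = np.fft.rfft(weighted, n_fft, axis=1)
    conv = np.fft.irfft(P * H[None, :], n_fft, axis=1)
    # 'same' part of the full convolution: offset n_det - 1
    return conv[:, n_det - 1 : 2 * n_det - 1] * spacing


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def forward_project(image: ImageSlice, geometry: ScanGeometry) -> Sinogram:
    """X-ray transform: line integrals of attenuation for each (alpha, u).

    The image is converted from HU to attenuation; rays run from the source
    (on a circle of radius R_F) to each flat-detector pixel.
    """
    if image.shape != geometry.image_shape():
        raise DataError(
            f"image shape {image.shape} does not match geometry grid {geometry.image_shape()}"
        )
    mu = hu_to_mu(image.pixels)
    out = np.zeros(geometry.sinogram_shape(), dtype=np.float64)
    _joseph_forward(
        np.ascontiguousarray(mu),
        float(geometry.pixel_size),
        geometry.n_views,
        geometry.n_det,
        float(geometry.R_F),
        float(geometry.R_D),
        float(geometry.det_pitch),
        out,
    )
    return Sinogram(values=out, geometry=geometry, role="clean")


def reconstruct(
    sinogram: Sinogram,
    geometry: ScanGeometry | None = None,
    filter_name: str = "shepp-logan",
) -> ImageSlice:
    """Fan-beam filtered backprojection, returning an image in HU.

    Steps: rescale the detector to a virtual detector through the isocenter,
    apply the fan-beam cosine weight, convolve each row with a band-limited
    ramp kernel, and backproject with the inverse-square distance weight over
    the full 360-degree scan (each line is measured twice, hence the 1/2).

    The operator is linear to floating-point tolerance, so reconstructions of
    sinogram differences are meaningful noise-only images; those are tagged
    ``noise_only`` and keep the HU *difference* scale (no -1000 offset).
    """
    geometry = geometry or sinogram.geometry
    values = np.asarray(sinogram.values, dtype=np.float64)
    if values.shape != geometry.sinogram_shape():
        raise DataError(
            f"sinogram shape {values.shape} does not match geometry {geometry.sinogram_shape()}"
        )
    if not np.isfinite(values).all():
        raise DataError("sinogram contains NaN/Inf; refusing to filter")

    scale = geometry.R_F / (geometry.R_F + geometry.R_D)
    du_virt = geometry.det_pitch * scale
    u_virt = geometry.det_coords * scale
    cosine = geometry.R_F / np.sqrt(geometry.R_F**2 + u_virt**2)

    filtered = _filter_rows(values * cosine[None, :], du_virt, filter_name)
    mu_img = np.zeros(geometry.image_shape(), dtype=np.float64)
    _fan_backproject(
        np.ascontiguousarray(filtered),
        float(geometry.pixel_size),
        geometry.n_y,
        geometry.n_x,
        float(geometry.R_F),
        float(du_virt),
        mu_img,
    )
    hu = mu_img * (1000.0 / MU_WATER)  # linear part of mu_to_hu
    if sinogram.role == "noise_only":
        role = "noise_only"
    else:
        hu = hu - 1000.0  # affine offset: mu=0 is air at -1000 HU
        role = {"clean": "ground_truth", "noisy": "low_dose", "target": "standard_dose"}[
            sinogram.role
        ]
    return ImageSlice(pixels=hu, pixel_size=geometry.pixel_size, role=role)
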