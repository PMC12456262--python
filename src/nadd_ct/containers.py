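"""In-memory containers for images and projection data.

``ImageSlice`` holds a reconstructed (or ground-truth) 2D slice in Hounsfield
units; ``Sinogram`` holds projection data p(alpha, u) as dimensionless line
integrals of the linear attenuation coefficient. Both carry a role tag so the
pipeline can distinguish clean, noisy, target and noise-only data, and both
validate their own invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import ScanGeometry

IMAGE_ROLES = ("ground_truth", "low_dose", "standard_dose", "noise_only", "prediction")
SINO_ROLES = ("clean", "noisy", "noise_only", "target")

HU_AIR = -1000.0
HU_MAX = 3000.0


class DataError(ValueError):
    """Raised for non-finite or out-of-contract array data."""


@dataclass
class ImageSlice:
    """A 2D CT slice in Hounsfield units.

    Noise-only slices are differences of reconstructions and may be negative;
    every other role is clipped-checked at >= -1000 HU.
    """

    pixels: np.ndarray
    pixel_size: float
    role: str = "ground_truth"
    subject_id: Optional[str] = None
    slice_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise DataError(f"ImageSlice expects a 2D array, got shape {self.pixels.shape}")
        if self.role not in IMAGE_ROLES:
            raise DataError(f"unknown image role {self.role!r}; expected one of {IMAGE_ROLES}")
        if not np.isfinite(self.pixels).all():
            raise DataError("ImageSlice contains NaN/Inf")
        if self.pixel_size <= 0:
            raise DataError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_role(self, role: str) -> "ImageSlice":
        return replace(self, role=role)

    def matches_geometry(self, geom: ScanGeometry) -> bool:
        return self.shape == geom.image_shape() and np.isclose(self.pixel_size, geom.pixel_size)


@dataclass
class Sinogram:
    """Projection data over (view angle, detector column).

    Values are line integrals of attenuation (dimensionless); they are
    non-negative for noiseless data up to noise-induced excursions, and must
    be finite for every role.
    """

    values: np.ndarray
    geometry: ScanGeometry
    role: str = "clean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.role not in SINO_ROLES:
            raise DataError(f"unknown sinogram role {self.role!r}; expected one of {SINO_ROLES}")
        if self.values.shape != self.geometry.sinogram_shape():
            raise DataError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{self.geometry.sinogram_shape()}"
            )
        if not np.isfinite(self.values).all():
            raise DataError("Sinogram contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, role: Optional[str] = None) -> "Sinogram":
        return Sinogram(values=values, geometry=self.geometry, role=role or self.role)
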