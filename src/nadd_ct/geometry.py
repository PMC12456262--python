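"""Fan-beam scan geometry for circular flat-detector CT.

A :class:`ScanGeometry` describes both the acquisition (source radius,
detector geometry, number of views) and the reconstruction grid. The
coordinate convention is fixed throughout the package:

* image pixel ``(0, 0)`` is top-left; the isocenter sits at the grid center;
* the view angle ``alpha`` is measured counterclockwise from the +x axis and
  gives the source position ``R_F * (cos(alpha), sin(alpha))``;
* the flat detector is centered at ``-R_D * (cos(alpha), sin(alpha))``,
  orthogonal to the source-isocenter line, with detector coordinate ``u``
  along ``(-sin(alpha), cos(alpha))``.

Two presets are provided: :data:`CLINICAL_GEOMETRY`, the clinical acquisition
(650/420 mm, 1024 views, 720 detector columns of 1.2 mm, 512x512 grid at
0.5 mm), and :data:`DESK_GEOMETRY`, a 128x128 / 256-view configuration small
enough for interactive use and test suites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


class GeometryError(ValueError):
    """Raised when a ScanGeometry is inconsistent."""


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition and reconstruction-grid parameters.

    Parameters
    ----------
    R_F : float
        Source-isocenter distance in mm.
    R_D : float
        Isocenter-detector distance in mm.
    n_views : int
        Number of projection angles covering 360 degrees.
    n_det : int
        Number of detector columns.
    det_pitch : float
        Detector pixel pitch in mm.
    n_x, n_y : int
        Reconstruction grid size in pixels.
    pixel_size : float
        Isotropic pixel size in mm.
    n_det_rows, det_row_pitch, n_z, slice_thickness : carried as metadata
        only; this package operates on the central slice, where the circular
        cone-beam (Feldkamp) reconstruction reduces exactly to 2D fan-beam
        filtered backprojection.
    """

    R_F: float = 650.0
    R_D: float = 420.0
    n_views: int = 1024
    n_det: int = 720
    det_pitch: float = 1.2
    n_x: int = 512
    n_y: int = 512
    pixel_size: float = 0.5
    # metadata only (3D acquisition bookkeeping, unused in 2D)
    n_det_rows: int = 256
    det_row_pitch: float = 1.2
    n_z: int = 1
    slice_thickness: float = 0.5

    def __post_init__(self) -> None:
        for name in ("R_F", "R_D", "det_pitch", "pixel_size"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive, got {getattr(self, name)}")
        for name, minimum in (("n_views", 4), ("n_det", 4), ("n_x", 4), ("n_y", 4)):
            if getattr(self, name) < minimum:
                raise GeometryError(f"{name} must be >= {minimum}, got {getattr(self, name)}")
        # the detector must subtend the circle circumscribing the image grid
        if self.fan_coverage_radius < self.fov_radius:
            raise GeometryError(
                "detector arc does not cover the reconstruction field of view: "
                f"fan coverage radius {self.fan_coverage_radius:.1f} mm < "
                f"grid circumscribed radius {self.fov_radius:.1f} mm "
                "(increase n_det or det_pitch)"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def magnification(self) -> float:
        """Geometric magnification (R_F + R_D) / R_F at the isocenter."""
        return (self.R_F + self.R_D) / self.R_F

    @property
    def det_width(self) -> float:
        """Physical detector width in mm."""
        return self.n_det * self.det_pitch

    @property
    def fov_radius(self) -> float:
        """Radius of the circle circumscribing the image grid, mm."""
        return 0.5 * math.hypot(self.n_x, self.n_y) * self.pixel_size

    @property
    def fan_coverage_radius(self) -> float:
        """Radius of the isocentric circle fully covered by the fan, mm."""
        half_fan = math.atan2(0.5 * self.det_width, self.R_F + self.R_D)
        return self.R_F * math.sin(half_fan)

    @property
    def view_angles(self):
        import numpy as np

        return np.arange(self.n_views) * (2.0 * np.pi / self.n_views)

    @property
    def det_coords(self):
        """Physical detector-column coordinates u (mm), centered."""
        import numpy as np

        return (np.arange(self.n_det) - (self.n_det - 1) / 2.0) * self.det_pitch

    def sinogram_shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_det)

    def image_shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


#: The clinical acquisition configuration.
CLINICAL_GEOMETRY = ScanGeometry()

#: Small geometry for fast tests and interactive experimentation.
DESK_GEOMETRY = ScanGeometry(
    R_F=650.0,
    R_D=420.0,
    n_views=256,
    n_det=272,
    det_pitch=2.4,
    n_x=128,
    n_y=128,
    pixel_size=2.0,
    n_det_rows=1,
    det_row_pitch=2.4,
)

PRESETS = {"clinical": CLINICAL_GEOMETRY, "desk": DESK_GEOMETRY}
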