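"""Synthetic 2D patient-slice phantoms.

The generator produces elliptical body cross-sections with lesion-like
elliptical inserts, in two regimes: *eccentric* slices (axis ratio >= 1.8,
like a shoulder section) whose long attenuation paths produce strongly
correlated streak noise after low-dose reconstruction, and *non-eccentric*
slices (axis ratio <= 1.2, like a head or abdomen section) with nearly
isotropic noise. Seeds are split hierarchically (cohort -> subject -> slice)
with :class:`numpy.random.SeedSequence`, so enlarging a cohort never perturbs
previously generated subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .containers import ImageSlice
from .geometry import ScanGeometry, DESK_GEOMETRY


class PhantomConfigError(ValueError):
    """Raised when a PhantomSpec violates its invariants."""


ECCENTRIC_MIN_RATIO = 1.8
NON_ECCENTRIC_MAX_RATIO = 1.2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic body cross-section.

    ``body_half_axes`` are the ellipse half-axes (a, b) in mm; ``eccentricity``
    must be consistent with their ratio (>= 1.8 for eccentric, <= 1.2 for
    non-eccentric). Inserts are non-overlapping hyper-/hypodense ellipses with
    contrasts drawn from ``insert_contrast`` (HU, applied with a random sign).
    """

    body_half_axes: tuple[float, float] = (120.0, 100.0)
    eccentricity: Literal["eccentric", "non_eccentric"] = "non_eccentric"
    n_inserts: int = 4
    insert_contrast: tuple[float, float] = (30.0, 300.0)
    background_hu: float = 40.0
    seed: int = 0

    def validate(self, geometry: ScanGeometry) -> None:
        a, b = self.body_half_axes
        if a <= 0 or b <= 0:
            raise PhantomConfigError(f"body_half_axes must be positive, got {self.body_half_axes}")
        fov = 0.5 * min(geometry.n_x, geometry.n_y) * geometry.pixel_size
        if max(a, b) > fov:
            raise PhantomConfigError(
                f"body_half_axes {self.body_half_axes} exceed the reconstruction "
                f"field of view (half-width {fov:.1f} mm)"
            )
        ratio = max(a, b) / min(a, b)
        if self.eccentricity == "eccentric" and ratio < ECCENTRIC_MIN_RATIO:
            raise PhantomConfigError(
                f"eccentric phantom requires axis ratio >= {ECCENTRIC_MIN_RATIO}, got {ratio:.2f}"
            )
        if self.eccentricity == "non_eccentric" and ratio > NON_ECCENTRIC_MAX_RATIO:
            raise PhantomConfigError(
                f"non_eccentric phantom requires axis ratio <= {NON_ECCENTRIC_MAX_RATIO}, "
                f"got {ratio:.2f}"
            )
        if self.n_inserts < 0:
            raise PhantomConfigError("n_inserts must be >= 0")
        lo, hi = self.insert_contrast
        if not (0 <= lo <= hi):
            raise PhantomConfigError(f"insert_contrast must satisfy 0 <= lo <= hi, got {self.insert_contrast}")
        if not (-1000.0 <= self.background_hu - hi and self.background_hu + hi <= 3000.0):
            raise PhantomConfigError("background +- insert contrast leaves the [-1000, 3000] HU range")


def _pixel_grid(geometry: ScanGeometry):
    ny, nx = geometry.image_shape()
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    x = (np.arange(nx) - cx) * geometry.pixel_size
    y = (cy - np.arange(ny)) * geometry.pixel_size
    return np.meshgrid(y, x, indexing="ij")


def _ellipse_coverage(yy, xx, cx, cy, a, b, theta, pixel_size, supersample=2):
    """Fractional pixel coverage of a rotated ellipse (anti-aliased edge)."""
    ct, st = math.cos(theta), math.sin(theta)
    # offsets of supersample points inside a pixel
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    cov = np.zeros(yy.shape, dtype=np.float64)
    for oy in offs:
        for ox in offs:
            dx = xx + ox * pixel_size - cx
            dy = yy + oy * pixel_size - cy
            xr = dx * ct + dy * st
            yr = -dx * st + dy * ct
            cov += ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0).astype(np.float64)
    return cov / supersample**2


def make_phantom(spec: PhantomSpec, geometry: ScanGeometry = DESK_GEOMETRY) -> ImageSlice:
    """Render a phantom slice in HU (air = -1000 outside the body).

    Deterministic for a fixed spec/seed. Inserts are placed by rejection
    sampling so they stay inside the body and do not overlap each other;
    edges are anti-aliased by 2x2 supersampled coverage so forward
    projections are not dominated by pixelization.
    """
    spec.validate(geometry)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    a, b = spec.body_half_axes
    yy, xx = _pixel_grid(geometry)

    body = _ellipse_coverage(yy, xx, 0.0, 0.0, a, b, 0.0, geometry.pixel_size)
    img = -1000.0 + body * (spec.background_hu + 1000.0)

    placed: list[tuple[float, float, float, float]] = []  # (cx, cy, a, b)
    attempts = 0
    while len(placed) < spec.n_inserts and attempts < 200 * max(spec.n_inserts, 1):
        attempts += 1
        ia = rng.uniform(0.04, 0.18) * min(a, b)
        ib = ia * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        # position well inside the body ellipse
        rad = math.sqrt(rng.uniform(0, 0.55))
        phi = rng.uniform(0, 2 * np.pi)
        icx = rad * (a - ia * 2.0) * math.cos(phi)
        icy = rad * (b - ia * 2.0) * math.sin(phi)
        if (icx / a) ** 2 + (icy / b) ** 2 > 0.7:
            continue
        if any(
            math.hypot(icx - px, icy - py) < 1.2 * (ia + pa)
            for px, py, pa, pb in placed
        ):
            continue
        contrast = rng.uniform(*spec.insert_contrast) * rng.choice([-1.0, 1.0])
        if spec.background_hu + contrast < -990.0:
            contrast = abs(contrast)
        cov = _ellipse_coverage(yy, xx, icx, icy, ia, ib, theta, geometry.pixel_size)
        img += cov * contrast
        placed.append((icx, icy, ia, ib))

    img = np.clip(img, -1000.0, 3000.0)
    return ImageSlice(pixels=img, pixel_size=geometry.pixel_size, role="ground_truth")


# ---------------------------------------------------------------------------
# cohorts and splits
# ---------------------------------------------------------------------------

def _subject_body(rng: np.random.Generator, eccentric: bool, geometry: ScanGeometry):
    """Draw per-subject body parameters (shared by all slices of the subject)."""
    fov = 0.5 * min(geometry.n_x, geometry.n_y) * geometry.pixel_size
    if eccentric:
        ratio = rng.uniform(1.9, 2.4)
        a = rng.uniform(0.75, 0.95) * fov
        b = a / ratio
    else:
        ratio = rng.uniform(1.0, 1.15)
        b = rng.uniform(0.5, 0.7) * fov
        a = b * ratio
    return (float(a), float(b)), float(rng.uniform(20.0, 60.0))


def make_cohort(
    n_subjects: int,
    slices_per_subject: int,
    mix: float = 0.5,
    seed: int = 0,
    geometry: ScanGeometry = DESK_GEOMETRY,
) -> list[tuple[str, ImageSlice]]:
    """Generate a cohort of (subject_id, slice) pairs.

    ``mix`` is the fraction of eccentric subjects. Slices of one subject share
    the body outline (per-subject spec) but have independently placed inserts
    (per-slice seeds), emulating neighbouring slices of one scan. Subject
    grouping is preserved so splits can be made by subject, never by slice.
    """
    if n_subjects < 1 or slices_per_subject < 1:
        raise PhantomConfigError("n_subjects and slices_per_subject must be >= 1")
    if not 0.0 <= mix <= 1.0:
        raise PhantomConfigError(f"mix must be in [0, 1], got {mix}")
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)
    n_ecc = int(round(mix * n_subjects))
    out: list[tuple[str, ImageSlice]] = []
    for s, sseq in enumerate(subject_seeds):
        eccentric = s < n_ecc
        sub_rng = np.random.default_rng(sseq)
        half_axes, background = _subject_body(sub_rng, eccentric, geometry)
        slice_seeds = sseq.spawn(slices_per_subject)
        subject_id = f"S{s:03d}"
        for k, kseq in enumerate(slice_seeds):
            slice_rng = np.random.default_rng(kseq)
            spec = PhantomSpec(
                body_half_axes=half_axes,
                eccentricity="eccentric" if eccentric else "non_eccentric",
                n_inserts=int(slice_rng.integers(2, 6)),
                background_hu=background,
                seed=int(kseq.generate_state(1)[0] % 2**31),
            )
            img = make_phantom(spec, geometry)
            img.subject_id = subject_id
            img.slice_id = f"{subject_id}.z{k:03d}"
            out.append((subject_id, img))
    return out


def split_cohort(
    subject_ids: list[str],
    ratios: tuple[int, int, int] = (27, 8, 4),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Partition subjects into disjoint train/val/test sets.

    Sizes follow ``ratios`` scaled to the number of subjects (largest-
    remainder rounding, train gets any leftover). With 39 subjects and the
    default 27:8:4 this returns exactly 27/8/4.
    """
    ids = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    n = len(ids)
    total = sum(ratios)
    sizes = [n * r // total for r in ratios]
    rem = n - sum(sizes)
    # distribute the remainder by largest fractional part
    fracs = sorted(range(3), key=lambda i: -(n * ratios[i] % total))
    for i in range(rem):
        sizes[fracs[i % 3]] += 1
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(ids))
    train = perm[: sizes[0]]
    val = perm[sizes[0] : sizes[0] + sizes[1]]
    test = perm[sizes[0] + sizes[1] :]
    return {"train": sorted(train), "val": sorted(val), "test": sorted(test)}
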