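"""Projection-domain Poisson noise injection and noise-only realizations.

The noise operator ``Q`` converts a sinogram of line integrals p to expected
photon counts ``I = I0 * exp(-p)``, replaces every count with an independent
Poisson draw of the same mean, and log-converts back:

    p_hat = -ln(max(k, floor) / I0),   k ~ Poisson(I).

``I0`` (photons per detector pixel) is the dose knob and is uniform over the
detector — heel effect, bowtie filtration and tube-current modulation are
deliberately outside this model. A low-dose scan uses ``I0_low =
dose_factor * I0_standard`` with ``dose_factor = 1/10`` by default (90% dose
reduction); the medium-dose preset uses 1/4.

Noise-only realizations are built *from the noisy low-dose sinogram q*, the
data actually available at inference time: ``r_n = Q(q) - q``. Reconstructing
each r_n with the (linear) FBP operator yields a zero-mean noise-only image
h_n carrying the patient-specific noise covariance — streaks along the long
axis of eccentric cross-sections.

Randomness uses Philox counter-based streams spawned per realization, so
realizations are order-independent and individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .containers import ImageSlice, Sinogram
from .geometry import ScanGeometry
from .projector import reconstruct


class DoseConfigError(ValueError):
    """Raised for invalid dose / realization configuration."""


MAX_REALIZATIONS_DEFAULT = 10


@dataclass(frozen=True)
class DoseConfig:
    """Dose and realization-count configuration.

    ``I0_standard`` is the standard-dose incident photon count per detector
    pixel; the absolute scale is a simulation choice (default 1e5),
    only the low/standard ratio is physically prescribed. ``count_floor``
    clamps Poisson draws before the log so photon starvation can never
    produce log(0).
    """

    I0_standard: float = 1.0e5
    dose_factor: float = 0.1
    count_floor: float = 0.5
    N: int = 10
    max_realizations: int = MAX_REALIZATIONS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I0_standard <= 0:
            raise DoseConfigError(f"I0_standard must be positive, got {self.I0_standard}")
        if not 0.0 < self.dose_factor <= 1.0:
            raise DoseConfigError(f"dose_factor must be in (0, 1], got {self.dose_factor}")
        if not 0.0 < self.count_floor < 1.0:
            raise DoseConfigError(f"count_floor must be in (0, 1), got {self.count_floor}")
        if not 0 <= self.N <= self.max_realizations:
            raise DoseConfigError(
                f"N={self.N} outside [0, {self.max_realizations}] "
                "(raise max_realizations to allow more channels)"
            )

    @property
    def I0_low(self) -> float:
        return self.dose_factor * self.I0_standard


MEDIUM_DOSE_FACTOR = 0.25  # 25% dose preset


def medium_dose(cfg: DoseConfig) -> DoseConfig:
    """The medium-dose (25%) variant of a configuration."""
    return replace(cfg, dose_factor=MEDIUM_DOSE_FACTOR)


# ---------------------------------------------------------------------------
# the operator Q
# ---------------------------------------------------------------------------

def to_intensity(p: np.ndarray | Sinogram, I0: float) -> np.ndarray:
    """Expected photon counts I = I0 * exp(-p) for line integrals p."""
    if I0 <= 0:
        raise DoseConfigError(f"I0 must be positive, got {I0}")
    values = p.values if isinstance(p, Sinogram) else np.asarray(p)
    return I0 * np.exp(-np.asarray(values, dtype=np.float64))


def inject_noise(
    p: Sinogram,
    I0: float,
    rng: np.random.Generator,
    count_floor: float = 0.5,
    role: str = "noisy",
) -> Sinogram:
    """Apply Q once: Poissonize the expected counts and log-convert back.

    The Poisson mean may be any non-negative real; counts are floored at
    ``count_floor`` before the log so the result is always finite. The draw
    is mean-preserving in counts (E[k] = I) and independent across pixels.
    """
    I = to_intensity(p, I0)
    k = rng.poisson(I).astype(np.float64)
    p_hat = -np.log(np.maximum(k, count_floor) / I0)
    return Sinogram(values=p_hat, geometry=p.geometry, role=role)


def make_dose_pair(
    p: Sinogram,
    cfg: DoseConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Sinogram, Sinogram]:
    """Generate the (low-dose input, standard-dose target) sinogram pair.

    Both arise from the *clean* sinogram p by independent applications of Q:
    the target also receives a small amount of noise (at I0_standard) so its
    texture is comparable to the input's, just much weaker.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    low_rng, tgt_rng = _spawn(rng, 2)
    q_low = inject_noise(p, cfg.I0_low, low_rng, cfg.count_floor, role="noisy")
    q_target = inject_noise(p, cfg.I0_standard, tgt_rng, cfg.count_floor, role="target")
    return q_low, q_target


@dataclass
class NoiseRealizationSet:
    """N paired noise-only sinograms r_n and their reconstructions h_n."""

    sinograms: list[Sinogram]
    images: list[ImageSlice]
    source_role: str
    config: DoseConfig
    realization_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sinograms) != len(self.images):
            raise DoseConfigError("realization sinograms and images must pair up 1:1")

    def __len__(self) -> int:
        return len(self.images)

    def stack(self) -> np.ndarray:
        """The h_n images as an (N, H, W) array."""
        return np.stack([im.pixels for im in self.images]) if self.images else np.empty((0, 0, 0))


def make_noise_realizations(
    q: Sinogram,
    cfg: DoseConfig,
    geometry: Optional[ScanGeometry] = None,
    rng: Optional[np.random.Generator] = None,
    I0_realization: Optional[float] = None,
) -> NoiseRealizationSet:
    """Generate N noise-only realizations r_n = Q(q) - q and images h_n.

    ``q`` must be the already-noisy measured sinogram — realizations are
    produced from data available at inference time, never from the clean p.
    The injection intensity defaults to ``cfg.I0_low`` and is *kept at the
    low-dose level even for medium-dose inputs*, reproducing the deliberate
    noise-level mismatch of the cross-dose experiment.
    """
    geometry = geometry or q.geometry
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    I0 = cfg.I0_low if I0_realization is None else I0_realization
    streams = _spawn(rng, cfg.N)
    sinos: list[Sinogram] = []
    images: list[ImageSlice] = []
    for n, stream in enumerate(streams):
        qq = inject_noise(q, I0, stream, cfg.count_floor, role="noisy")
        r = Sinogram(values=qq.values - q.values, geometry=geometry, role="noise_only")
        h = reconstruct(r, geometry)
        h.slice_id = f"r{n}"
        sinos.append(r)
        images.append(h)
    return NoiseRealizationSet(
        sinograms=sinos, images=images, source_role=q.role, config=cfg
    )


def directional_anisotropy(noise_image: np.ndarray | ImageSlice, roi: Optional[tuple] = None) -> float:
    """Streak-orientation statistic of a noise-only image.

    Returns the ratio of high-pass energy across rows to that across columns,
    E[(d/dy n)^2] / E[(d/dx n)^2]. Streaks oriented along x (the long axis of
    a laterally eccentric cross-section) vary rapidly in y, giving a ratio
    well above 1; isotropic noise gives a ratio near 1.
    """
    h = noise_image.pixels if isinstance(noise_image, ImageSlice) else np.asarray(noise_image)
    if roi is not None:
        h = h[roi]
    dy = np.diff(h, axis=0)
    dx = np.diff(h, axis=1)
    return float((dy**2).mean() / (dx**2).mean())


def _spawn(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    """Independent Philox child streams (counter-based, order-independent)."""
    seeds = rng.integers(0, 2**31 - 1, size=max(n, 1))
    return [np.random.Generator(np.random.Philox(key=int(s))) for s in seeds[:n]]
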