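"""The CNN10 denoiser family and channel-augmentation contract.

CNN10 is a three-layer convolutional network (kernels s1=9, s2=3, s3=5;
feature counts n1=64, n2=32) trained to minimize the MSE between its
prediction and the standard-dose target. Its noise-augmented variant,
written ``CNN10+N``, differs only in the first layer, which accepts the
low-dose image plus N noise-only channels (1+N input channels in total).

The closed-form trainable-parameter count is

    n1*s1^2*(1+N) + n1  +  n2*s2^2*n1 + n2  +  s3^2*n2 + 1,

which for the canonical CNN10+10 gives 76,353 parameters. The fairness
baseline widens the unaugmented network's first layer to the smallest n1
whose count reaches that of the augmented network (n1=205, 76,683
parameters), isolating the effect of augmentation from raw capacity.

The network itself runs on NumPy: same-padded convolutions, ReLU after the
first two layers, a linear output layer, He fan-in initialization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace, asdict
from typing import Optional

import numpy as np

from ._conv import conv2d, conv2d_backward


class NetworkSpecError(ValueError):
    """Raised for invalid architecture hyper-structure."""


@dataclass(frozen=True)
class NetworkSpec:
    """Hyper-structure of a CNN10-family denoiser.

    ``N`` is the number of noise-only input channels; the input layer sees
    1+N channels, the output is always a single denoised channel.
    """

    s1: int = 9
    s2: int = 3
    s3: int = 5
    n1: int = 64
    n2: int = 32
    N: int = 0
    nonlinearity: str = "relu"
    padding: str = "same"

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise NetworkSpecError(f"{name} must be an odd kernel size >= 1, got {k}")
        for name in ("n1", "n2"):
            if getattr(self, name) < 1:
                raise NetworkSpecError(f"{name} must be >= 1")
        if self.N < 0:
            raise NetworkSpecError(f"N must be >= 0, got {self.N}")
        if self.nonlinearity != "relu" or self.padding != "same":
            raise NetworkSpecError("only relu nonlinearity with same padding is implemented")

    @property
    def in_channels(self) -> int:
        return 1 + self.N

    @property
    def label(self) -> str:
        """Subscript notation: 'CNN10' unaugmented, 'CNN10+N' augmented."""
        return "CNN10" if self.N == 0 else f"CNN10+{self.N}"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "NetworkSpec":
        m = re.fullmatch(r"CNN10(?:\+(\d+))?", label)
        if not m:
            raise NetworkSpecError(f"cannot parse architecture label {label!r}")
        return cls(N=int(m.group(1) or 0), **kwargs)


CANONICAL_CNN10 = NetworkSpec()


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count of the three-layer network."""
    return (
        spec.n1 * spec.s1**2 * (1 + spec.N)
        + spec.n1
        + spec.n2 * spec.s2**2 * spec.n1
        + spec.n2
        + spec.s3**2 * spec.n2
        + 1
    )


def adjust_width_for_parity(base: NetworkSpec, reference_N: int) -> NetworkSpec:
    """Widen an unaugmented network to parameter parity with its augmented twin.

    Returns ``base`` with the smallest n1 such that the single-channel
    network has at least as many parameters as ``base`` with N=reference_N.
    For the canonical CNN10 and reference_N=10 this gives n1=205.
    """
    if base.N != 0:
        raise NetworkSpecError("parity adjustment starts from an unaugmented (N=0) base")
    target = count_parameters(replace(base, N=reference_N))
    n1 = base.n1
    while count_parameters(replace(base, n1=n1)) < target:
        n1 += 1
    return replace(base, n1=n1)


def augment_input_channels(backbone, N: int):
    """Widen a backbone's input layer from 1 to 1+N channels.

    The augmentation contract is architecture-agnostic: any backbone that
    declares its first-layer input-channel count can be augmented; nothing
    but that count changes, so the parameter delta is exactly
    (first-layer kernel volume) x (first-layer features) x N. For a
    :class:`NetworkSpec` this returns the spec with ``N`` set; third-party
    backbones plug in via :class:`BackboneDescriptor`.
    """
    if N < 0:
        raise NetworkSpecError("N must be >= 0")
    if isinstance(backbone, NetworkSpec):
        return replace(backbone, N=N)
    if isinstance(backbone, BackboneDescriptor):
        return replace(backbone, input_channels=1 + N)
    raise NetworkSpecError(
        f"unsupported backbone {type(backbone).__name__}: it must declare a 2D image "
        "input layer (NetworkSpec or BackboneDescriptor)"
    )


@dataclass(frozen=True)
class BackboneDescriptor:
    """Minimal description of a third-party denoiser's input layer.

    Allows external architectures (deep residual networks, adversarially
    trained denoisers, ...) to participate in the augmentation contract
    without this package knowing their internals.
    """

    name: str
    input_channels: int
    first_layer_kernel: int
    first_layer_features: int

    def __post_init__(self) -> None:
        if self.input_channels < 1 or self.first_layer_kernel < 1 or self.first_layer_features < 1:
            raise NetworkSpecError("backbone input layer fields must be >= 1")

    def augmentation_parameter_delta(self, N: int) -> int:
        return self.first_layer_kernel**2 * self.first_layer_features * N


# ---------------------------------------------------------------------------
# the network itself
# ---------------------------------------------------------------------------

class CNN10:
    """Three-layer convolutional denoiser running on NumPy.

    conv(s1, 1+N -> n1) + ReLU, conv(s2, n1 -> n2) + ReLU, conv(s3, n2 -> 1),
    all same-padded so output spatial size equals input size. Operates on
    normalized image stacks of shape (batch, 1+N, H, W).
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        cin = spec.in_channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.W1 = he((spec.n1, cin, spec.s1, spec.s1), cin * spec.s1**2)
        # silent-start augmentation: noise-channel weights begin at zero, so
        # an augmented network starts functionally identical to an
        # unaugmented one and recruits the noise channels only where their
        # gradient says they reduce the loss
        if spec.N > 0:
            self.W1[:, 1:, :, :] = 0.0
        self.b1 = np.zeros(spec.n1, dtype=np.float32)
        self.W2 = he((spec.n2, spec.n1, spec.s2, spec.s2), spec.n1 * spec.s2**2)
        self.b2 = np.zeros(spec.n2, dtype=np.float32)
        # linear output layer: fan-in scaled (no ReLU gain)
        self.W3 = rng.normal(
            0.0, np.sqrt(1.0 / (spec.n2 * spec.s3**2)), size=(1, spec.n2, spec.s3, spec.s3)
        ).astype(np.float32)
        self.b3 = np.zeros(1, dtype=np.float32)
        self._cache = None

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        names = ["W1", "b1", "W2", "b2", "W3", "b3"]
        for name, p in zip(names, params, strict=True):
            current = getattr(self, name)
            if p.shape != current.shape:
                raise NetworkSpecError(f"parameter {name} shape {p.shape} != {current.shape}")
            setattr(self, name, p.astype(np.float32).copy())

    def n_parameters(self) -> int:
        """Enumerated trainable-weight count (cross-checks the closed form)."""
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise NetworkSpecError(
                f"expected input of shape (batch, {self.spec.in_channels}, H, W), got {x.shape}"
            )
        z1, cols1 = conv2d(x, self.W1, self.b1)
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = conv2d(a1, self.W2, self.b2)
        a2 = np.maximum(z2, 0.0)
        out, cols3 = conv2d(a2, self.W3, self.b3)
        if cache:
            self._cache = (x.shape, z1, cols1, a1.shape, z2, cols2, a2.shape, cols3)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, cache=False)

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients w.r.t. parameters for the last cached forward pass."""
        if self._cache is None:
            raise NetworkSpecError("backward called before forward")
        x_shape, z1, cols1, a1_shape, z2, cols2, a2_shape, cols3 = self._cache
        da2, dW3, db3 = conv2d_backward(dout.astype(np.float32), cols3, self.W3, a2_shape)
        dz2 = da2 * (z2 > 0)
        da1, dW2, db2 = conv2d_backward(dz2, cols2, self.W2, a1_shape)
        dz1 = da1 * (z1 > 0)
        _, dW1, db1 = conv2d_backward(dz1, cols1, self.W1, x_shape, need_dx=False)
        return [dW1, db1, dW2, db2, dW3, db3]


def build_cnn10(spec: NetworkSpec, seed: int = 0) -> CNN10:
    """Construct the CNN10 denoiser for a given hyper-structure."""
    return CNN10(spec, seed=seed)
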