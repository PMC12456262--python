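"""Minimal 2D convolution engine (forward + gradients) on NumPy.

Same-padding cross-correlation via im2col and BLAS matmul; gradients via the
transposed col2im scatter. Shapes follow the (batch, channel, height, width)
convention. float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patches under zero same-padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # windows: (B, C, H, W, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols, dtype=np.float32)


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Same-padded conv: x (B,Cin,H,W), weight (Cout,Cin,k,k), bias (Cout,)."""
    b, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    if cin != c:
        raise ValueError(f"conv2d expects {cin} input channels, got {c}")
    cols = _im2col(x, k)
    wm = weight.reshape(cout, cin * k * k)
    out = cols @ wm.T + bias[None, :]
    return out.reshape(b, h, w, cout).transpose(0, 3, 1, 2), cols


def conv2d_backward(
    dout: np.ndarray,
    cols: np.ndarray,
    weight: np.ndarray,
    x_shape: tuple[int, int, int, int],
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of conv2d: returns (dx, dweight, dbias).

    ``need_dx=False`` skips the input gradient (the costly col2im scatter),
    which the first layer of a network never needs.
    """
    b, c, h, w = x_shape
    cout, cin, k, _ = weight.shape
    dm = dout.transpose(0, 2, 3, 1).reshape(b * h * w, cout)
    dweight = (dm.T @ cols).reshape(weight.shape)
    dbias = dm.sum(axis=0)
    if not need_dx:
        return None, dweight, dbias
    dcols = dm @ weight.reshape(cout, cin * k * k)
    # col2im scatter-add back onto the padded input grid
    p = k // 2
    dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    dcols = dcols.reshape(b, h, w, c, k, k)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
    dx = dxp[:, :, p : p + h, p : p + w] if p else dxp
    return dx, dweight, dbias
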