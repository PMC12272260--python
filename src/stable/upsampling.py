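"""Learnable dynamic upsampling by offset grid sampling.

Fixed upsampling resamples a low-resolution feature map ``X ∈ R^{C×H×W}`` at a
uniform grid of coordinates.  The dynamic operator instead *learns* where to
sample: a 1×1 convolution predicts per-output-pixel displacements, pixel
shuffle rearranges them to the upsampled resolution, and the feature map is
bilinearly resampled at ``S = G + O`` — the uniform grid plus the learned
offsets.  With the offset head initialized to zero the operator starts out as
exact bilinear interpolation and can only improve on it during training.

Coordinate convention: 0-based pixel centers; x = column, y = row; offsets in
input-pixel units.  Grids are ``(2, sH, sW)`` with channel 0 = x, channel 1 = y.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, as_tensor
from .nn import Conv2d, Module

__all__ = [
    "make_uniform_grid",
    "pixel_shuffle",
    "predict_offsets",
    "grid_sample_bilinear",
    "dynamic_upsample",
    "DynamicUpsample",
    "BilinearUpsample",
]


def make_uniform_grid(h: int, w: int, s: int) -> np.ndarray:
    """Uniform sampling grid for upsampling ``(H, W)`` by integer factor ``s``.

    Output pixel ``(u, v)`` maps to input coordinate
    ``x = (v + 0.5)/s - 0.5``, ``y = (u + 0.5)/s - 0.5`` (pixel-center
    convention), so ``s = 1`` yields the identity grid.
    """
    if h < 1 or w < 1 or s < 1:
        raise ValueError("H, W and s must be positive")
    ys = (np.arange(s * h, dtype=np.float64) + 0.5) / s - 0.5
    xs = (np.arange(s * w, dtype=np.float64) + 0.5) / s - 0.5
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    return np.stack([gx, gy])


def pixel_shuffle(x, s: int):
    """Rearrange ``(C·s², H, W)`` into ``(C, sH, sW)`` (value-preserving bijection)."""
    if isinstance(x, Tensor):
        return x.pixel_shuffle(s)
    x = np.asarray(x)
    return Tensor(x).pixel_shuffle(s).data


def grid_sample_bilinear(x, grid):
    """Bilinear resampling of ``(C, H, W)`` at grid positions (border-clamped)."""
    if isinstance(x, Tensor) or isinstance(grid, Tensor):
        return as_tensor(x).grid_sample(as_tensor(grid))
    x = np.asarray(x)
    return Tensor(x).grid_sample(Tensor(np.asarray(grid))).data


def predict_offsets(x, weight, bias, s: int, offset_scale: float = 1.0):
    """Offset grid ``O = pixel_shuffle(Conv1x1(X; θ))`` of shape ``(2, sH, sW)``.

    ``weight`` must map the feature channels to ``2s²`` offset channels.
    """
    xt = as_tensor(x)
    wt = as_tensor(weight)
    bt = as_tensor(bias) if bias is not None else None
    cout = wt.shape[0]
    if cout != 2 * s * s:
        raise ValueError(f"offset head has {cout} output channels, expected 2*s^2={2 * s * s}")
    raw = xt.conv2d(wt, bt)  # (2s^2, H, W)
    off = raw.pixel_shuffle(s)
    if offset_scale != 1.0:
        off = off * float(offset_scale)
    if isinstance(x, Tensor) or isinstance(weight, Tensor):
        return off
    return off.data


def dynamic_upsample(x, weight, bias, s: int, offset_scale: float = 1.0):
    """Upsample ``(C, H, W)`` to ``(C, sH, sW)`` at learned positions ``G + O``."""
    xt = as_tensor(x)
    _, h, w = xt.shape
    grid = make_uniform_grid(h, w, s).astype(xt.dtype)
    off = predict_offsets(xt, as_tensor(weight),
                          as_tensor(bias) if bias is not None else None,
                          s, offset_scale)
    sgrid = as_tensor(grid) + as_tensor(off)
    out = xt.grid_sample(sgrid)
    if isinstance(x, Tensor):
        return out
    return out.data


class DynamicUpsample(Module):
    """Module form: zero-initialized offset head, so training starts bilinear."""

    def __init__(self, channels: int, s: int = 2, offset_scale: float = 1.0,
                 rng: np.random.Generator = None):
        self.s = s
        self.offset_scale = offset_scale
        self.offset_head = Conv2d(channels, 2 * s * s, kernel_size=1, zero_init=True)

    def forward(self, x: Tensor) -> Tensor:
        return dynamic_upsample(x, self.offset_head.weight, self.offset_head.bias,
                                self.s, self.offset_scale)


class BilinearUpsample(Module):
    """Fixed bilinear upsampling (the ablation alternative; no parameters)."""

    def __init__(self, s: int = 2):
        self.s = s

    def forward(self, x: Tensor) -> Tensor:
        _, h, w = x.shape
        grid = as_tensor(make_uniform_grid(h, w, self.s).astype(x.dtype))
        return x.grid_sample(grid)
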