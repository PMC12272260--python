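"""Minimal reverse-mode automatic differentiation on numpy arrays.

The translation networks, the dynamic upsampling operator and the GAN
objectives are all built from the small op set defined here.  Tensors wrap
``numpy.ndarray`` values; every op records a backward closure and
``Tensor.backward()`` runs reverse-mode accumulation over the recorded graph.

Conventions
-----------
* Image/feature tensors are channel-first ``(C, H, W)`` with batch size 1
  (the training recipe uses batch 1 throughout).
* dtype follows the input data; float32 is used for training, float64 for
  finite-difference gradient checks.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    # --------------------------------------------------------------- backward
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        on_stack = {id(self)}
        # iterative DFS post-order (graphs can be deep)
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and id(p) not in on_stack and p.requires_grad:
                    stack.append((p, iter(p._parents)))
                    on_stack.add(id(p))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                on_stack.discard(id(node))
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(
            self.data / other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------ elementwise
    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        out._backward = bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out.data)

        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(
            np.where(self.data > 0, self.data, slope * self.data),
            self.requires_grad,
            (self,),
        )

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, slope).astype(self.dtype))

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s.astype(self.dtype), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out.data * (1.0 - out.data))

        out._backward = bw
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    # ----------------------------------------------------------- spatial ops
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0) -> "Tensor":
        """2D convolution on a single ``(Cin, H, W)`` input.

        ``weight`` is ``(Cout, Cin, kh, kw)``; zero padding; implemented via
        im2col + matmul so the heavy lifting is a single GEMM.
        """
        x = self.data
        w = weight.data
        cout, cin, kh, kw = w.shape
        if x.shape[0] != cin:
            raise ValueError(f"conv2d: input has {x.shape[0]} channels, weight expects {cin}")
        h, w_in = x.shape[1:]
        if padding:
            xp = np.zeros((cin, h + 2 * padding, w_in + 2 * padding), dtype=x.dtype)
            xp[:, padding : padding + h, padding : padding + w_in] = x
        else:
            xp = x
        _, hp, wp = xp.shape
        ho = (hp - kh) // stride + 1
        wo = (wp - kw) // stride + 1
        # im2col in (Cin*kh*kw, Ho*Wo) layout, filled by kh*kw strided copies
        cols = np.empty((cin, kh, kw, ho, wo), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, i, j] = xp[:, i : i + ho * stride : stride,
                                   j : j + wo * stride : stride]
        cols = cols.reshape(cin * kh * kw, ho * wo)
        wmat = w.reshape(cout, -1)
        y = wmat @ cols  # (Cout, Ho*Wo)
        if bias is not None:
            y = y + bias.data[:, None]
        out_data = y.reshape(cout, ho, wo)
        req = self.requires_grad or weight.requires_grad or (
            bias is not None and bias.requires_grad
        )
        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor(out_data, req, parents)

        def bw(g):
            gm = g.reshape(cout, -1)  # (Cout, Ho*Wo)
            if weight.requires_grad:
                weight._accum((gm @ cols.T).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gm.sum(axis=1))
            if self.requires_grad:
                dcols = (wmat.T @ gm).reshape(cin, kh, kw, ho, wo)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, i : i + ho * stride : stride,
                            j : j + wo * stride : stride] += dcols[:, i, j]
                if padding:
                    dxp = dxp[:, padding:-padding, padding:-padding]
                self._accum(dxp)

        out._backward = bw
        return out

    def maxpool2x2(self) -> "Tensor":
        c, h, w = self.data.shape
        if h % 2 or w % 2:
            raise ValueError("maxpool2x2 requires even spatial dimensions")
        xr = self.data.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        out = Tensor(out_data, self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            dxr = np.zeros((c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
            dx = dxr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4)
            self._accum(np.ascontiguousarray(dx).reshape(c, h, w))

        out._backward = bw
        return out

    def pixel_shuffle(self, s: int) -> "Tensor":
        """Rearrange ``(C*s^2, H, W)`` into ``(C, sH, sW)``."""
        cs, h, w = self.data.shape
        if cs % (s * s):
            raise ValueError(f"pixel_shuffle: {cs} channels not divisible by s^2={s * s}")
        c = cs // (s * s)
        out_data = (
            self.data.reshape(c, s, s, h, w)
            .transpose(0, 3, 1, 4, 2)
            .reshape(c, h * s, w * s)
        )
        out = Tensor(np.ascontiguousarray(out_data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                gg = g.reshape(c, h, s, w, s).transpose(0, 2, 4, 1, 3).reshape(cs, h, w)
                self._accum(np.ascontiguousarray(gg))

        out._backward = bw
        return out

    def grid_sample(self, grid: "Tensor") -> "Tensor":
        """Bilinear sampling of ``(C, H, W)`` at ``grid`` positions.

        ``grid`` is ``(2, sH, sW)`` — channel 0 holds x (column) and channel 1
        y (row) coordinates in input-pixel units, 0-based pixel centers.
        Out-of-range positions are clamped to the border before interpolating;
        differentiable w.r.t. both the feature map and the grid.
        """
        x = self.data
        c, h, w = x.shape
        gx_raw = grid.data[0]
        gy_raw = grid.data[1]
        gx = np.clip(gx_raw, 0.0, w - 1.0)
        gy = np.clip(gy_raw, 0.0, h - 1.0)
        x0 = np.clip(np.floor(gx), 0, max(w - 2, 0)).astype(np.intp)
        y0 = np.clip(np.floor(gy), 0, max(h - 2, 0)).astype(np.intp)
        x1 = np.minimum(x0 + 1, w - 1)
        y1 = np.minimum(y0 + 1, h - 1)
        wx = (gx - x0).astype(x.dtype)
        wy = (gy - y0).astype(x.dtype)
        xf = x.reshape(c, h * w)
        i00 = y0 * w + x0
        i01 = y0 * w + x1
        i10 = y1 * w + x0
        i11 = y1 * w + x1
        v00 = xf[:, i00]
        v01 = xf[:, i01]
        v10 = xf[:, i10]
        v11 = xf[:, i11]
        w00 = (1 - wx) * (1 - wy)
        w01 = wx * (1 - wy)
        w10 = (1 - wx) * wy
        w11 = wx * wy
        out_data = v00 * w00 + v01 * w01 + v10 * w10 + v11 * w11
        out = Tensor(out_data, self.requires_grad or grid.requires_grad, (self, grid))

        def bw(g):
            if self.requires_grad:
                n = c * h * w
                off = (np.arange(c, dtype=np.intp) * (h * w))[:, None, None]
                dx = np.zeros(n, dtype=np.float64)
                for idx, ww in ((i00, w00), (i01, w01), (i10, w10), (i11, w11)):
                    dx += np.bincount((idx[None] + off).ravel(),
                                      weights=(g * ww).ravel(), minlength=n)
                self._accum(dx.reshape(c, h, w).astype(g.dtype))
            if grid.requires_grad:
                dgx = ((v01 - v00) * (1 - wy) + (v11 - v10) * wy) * g
                dgy = ((v10 - v00) * (1 - wx) + (v11 - v01) * wx) * g
                dgx = dgx.sum(axis=0)
                dgy = dgy.sum(axis=0)
                # clamping: no gradient where the raw coordinate was out of range
                dgx[(gx_raw < 0) | (gx_raw > w - 1)] = 0.0
                dgy[(gy_raw < 0) | (gy_raw > h - 1)] = 0.0
                grid._accum(np.stack([dgx, dgy]))

        out._backward = bw
        return out

    def batchnorm2d(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Per-channel normalization over the spatial axes of ``(C, H, W)``.

        With batch size 1 the statistics are spatial (instance) statistics,
        which is what 'batch normalization' reduces to in this training recipe.
        """
        x = self.data
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        gam = gamma.data[:, None, None]
        out_data = gam * xhat + beta.data[:, None, None]
        req = self.requires_grad or gamma.requires_grad or beta.requires_grad
        out = Tensor(out_data.astype(x.dtype), req, (self, gamma, beta))

        def bw(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(1, 2)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(1, 2)))
            if self.requires_grad:
                n = x.shape[1] * x.shape[2]
                gh = g * gam  # dL/dxhat
                t = gh - gh.mean(axis=(1, 2), keepdims=True) - xhat * (
                    (gh * xhat).mean(axis=(1, 2), keepdims=True)
                )
                self._accum((t * inv).astype(x.dtype))

        out._backward = bw
        return out


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype)
    return Tensor(arr)


def concat(tensors: list, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (used for U-Net skip connections)."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out._backward = bw
    return out
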