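"""Neural-network building blocks and the AdamW optimizer.

Thin module system over :mod:`stable._tensor`: modules hold named parameters,
compose, and serialize to flat ``{name: array}`` dicts for checkpointing.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "AdamW"]


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter discovery, grad zeroing, state (de)serialization."""

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) - set(state)
            extra = set(state) - set(own)
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"parameter {name}: checkpoint shape {arr.shape} != model {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """2D convolution layer, He-normal initialized (or zero for offset heads)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator = None,
                 zero_init: bool = False):
        self.stride = stride
        self.padding = padding
        k = kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, k, k), dtype=np.float32)
        else:
            rng = rng if rng is not None else np.random.default_rng()
            std = np.sqrt(2.0 / (in_channels * k * k))
            w = rng.normal(0.0, std, (out_channels, in_channels, k, k)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.batchnorm2d(self.gamma, self.beta, eps=self.eps)


class AdamW:
    """AdamW with decoupled weight decay (default decay 0, per the recipe)."""

    def __init__(self, params: list, lr: float = 3e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        out = {"t": self.t}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m.copy()
            out[f"v{i}"] = v.copy()
        return out

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m{i}"]).copy()
            self.v[i] = np.asarray(state[f"v{i}"]).copy()
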