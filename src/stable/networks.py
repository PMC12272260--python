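"""Encoders, decoders, generator pairs and discriminators.

Each translation generator is an encoder–decoder pair.  The encoder maps an
image into a shared feature domain ``Z`` with ``CZ`` channels at the *same*
spatial resolution as the input — full-resolution features are what make
pixel-level information consistency possible.  Both encoder and decoder are
U-shaped: a contracting path of double-3×3-conv blocks with 2×2 max pooling,
and an expansive path that upsamples (dynamic upsampling by default, bilinear
as an ablation), concatenates the skip features and applies another double
conv.  Discriminators are patch-based least-squares critics built from strided
4×4 convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, as_tensor, concat
from .nn import BatchNorm2d, Conv2d, Module, Parameter
from .upsampling import BilinearUpsample, DynamicUpsample

__all__ = [
    "EncoderSpec",
    "DecoderSpec",
    "modulate_demodulate",
    "UNet",
    "GeneratorPair",
    "Discriminator",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of a domain encoder (image -> full-resolution features)."""

    in_channels: int
    levels: tuple = (8, 16, 32)
    feature_channels: int = 8
    use_batchnorm: bool = False
    use_modulation: bool = True
    upsampler: str = "dynamic"  # "dynamic" | "bilinear"

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError("at least two spatial levels are required")
        if self.feature_channels < 1:
            raise ValueError("feature_channels must be >= 1")


@dataclass(frozen=True)
class DecoderSpec:
    """Architecture of a domain decoder (features -> image)."""

    out_channels: int
    levels: tuple = (8, 16, 32)
    feature_channels: int = 8
    use_batchnorm: bool = False
    use_modulation: bool = True
    upsampler: str = "dynamic"
    final_activation: str = "none"  # "none" | "sigmoid"

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValueError("at least two spatial levels are required")


def modulate_demodulate(weight, scales, eps: float = 1e-8):
    """Scale conv weights per input channel, then renormalize per output filter.

    Every output filter of the returned weight has (close to) unit L2 norm, so
    uniformly rescaling ``scales`` has no net effect; with all scales equal to
    one this is pure per-filter weight normalization, which suppresses the
    droplet-like artifacts that unnormalized generators can develop.
    """
    w = as_tensor(weight)
    s = as_tensor(scales)
    cin = w.shape[1]
    if s.shape != (cin,):
        raise ValueError(f"need one positive scale per input channel ({cin}), got {s.shape}")
    wm = w * s.reshape(1, cin, 1, 1)
    norm = ((wm * wm).sum(axis=(1, 2, 3), keepdims=True) + eps).sqrt()
    return wm / norm


class ModConv2d(Module):
    """3×3 conv with learned self-modulation scales and weight demodulation.

    Demodulated filters have unit L2 norm, which would shrink activation
    variance by ~1/2 per ReLU layer and let a deep U-Net decay to its biases;
    a fixed He-style √2 gain after demodulation keeps the forward pass
    variance-preserving without changing the normalization itself.
    """

    GAIN = float(np.sqrt(2.0))

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=1,
                 rng: np.random.Generator = None):
        self.conv = Conv2d(in_channels, out_channels, kernel_size, padding=padding, rng=rng)
        self.scales = Parameter(np.ones(in_channels, dtype=np.float32))
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        w = modulate_demodulate(self.conv.weight, self.scales) * self.GAIN
        return x.conv2d(w, self.conv.bias, padding=self.padding)


class ConvBlock(Module):
    """Two 3×3 convolutions, each optionally batch-normalized, each ReLU-activated."""

    def __init__(self, in_channels, out_channels, use_batchnorm, use_modulation,
                 rng: np.random.Generator = None):
        self.conv1 = (ModConv2d(in_channels, out_channels, rng=rng) if use_modulation
                      else Conv2d(in_channels, out_channels, 3, padding=1, rng=rng))
        self.conv2 = (ModConv2d(out_channels, out_channels, rng=rng) if use_modulation
                      else Conv2d(out_channels, out_channels, 3, padding=1, rng=rng))
        self.bn1 = BatchNorm2d(out_channels) if use_batchnorm else None
        self.bn2 = BatchNorm2d(out_channels) if use_batchnorm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = x.relu()
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return x.relu()


def _make_upsampler(kind: str, channels: int, rng) -> Module:
    if kind == "dynamic":
        return DynamicUpsample(channels, s=2, rng=rng)
    if kind == "bilinear":
        return BilinearUpsample(s=2)
    raise ValueError(f"unknown upsampler {kind!r} (expected 'dynamic' or 'bilinear')")


class UNet(Module):
    """U-shaped network preserving spatial resolution end to end.

    Used both as encoder (image -> CZ features) and decoder (features ->
    image); the two differ only in channel counts and final activation.
    """

    def __init__(self, in_channels: int, levels, out_channels: int,
                 use_batchnorm: bool = False, use_modulation: bool = True,
                 upsampler: str = "dynamic", final_activation: str = "none",
                 rng: np.random.Generator = None):
        levels = tuple(levels)
        self.levels = levels
        self.final_activation = final_activation
        n = len(levels)
        self.down = []
        c = in_channels
        for width in levels:
            self.down.append(ConvBlock(c, width, use_batchnorm, use_modulation, rng))
            c = width
        self.ups = []
        self.up_blocks = []
        for i in range(n - 2, -1, -1):
            self.ups.append(_make_upsampler(upsampler, levels[i + 1], rng))
            self.up_blocks.append(
                ConvBlock(levels[i + 1] + levels[i], levels[i],
                          use_batchnorm, use_modulation, rng)
            )
        # the head is demodulated too when modulation is on: unit-norm filters
        # cannot shrink to zero, which protects the feature maps (and thus the
        # information-consistency constraint) from trivial constant collapse
        self.head = (ModConv2d(levels[0], out_channels, kernel_size=1, padding=0, rng=rng)
                     if use_modulation else Conv2d(levels[0], out_channels, 1, rng=rng))

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        n = len(self.levels)
        _, h, w = x.shape
        factor = 2 ** (n - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^(levels-1)={factor}; "
                f"reflect-pad to the nearest multiple (see training.pad_to_multiple) "
                f"and crop the output back"
            )
        skips = []
        for i, block in enumerate(self.down):
            x = block(x)
            if i < n - 1:
                skips.append(x)
                x = x.maxpool2x2()
        for up, block, skip in zip(self.ups, self.up_blocks, reversed(skips)):
            x = up(x)
            x = concat([x, skip], axis=0)
            x = block(x)
        x = self.head(x)
        if self.final_activation == "sigmoid":
            x = x.sigmoid()
        return x


class Encoder(UNet):
    def __init__(self, spec: EncoderSpec, rng=None):
        super().__init__(spec.in_channels, spec.levels, spec.feature_channels,
                         spec.use_batchnorm, spec.use_modulation, spec.upsampler,
                         "none", rng)
        self.spec = spec


class Decoder(UNet):
    def __init__(self, spec: DecoderSpec, rng=None):
        super().__init__(spec.feature_channels, spec.levels, spec.out_channels,
                         spec.use_batchnorm, spec.use_modulation, spec.upsampler,
                         spec.final_activation, rng)
        self.spec = spec


class GeneratorPair(Module):
    """The four translation networks: encoders G_A, G_B and decoders F_A, F_B.

    ``translate(x, "a2b")`` computes ``F_B(G_A(x))`` and the reverse direction
    ``F_A(G_B(x))``; ``encode`` exposes the shared-domain feature maps used by
    the information-consistency constraint.
    """

    def __init__(self, enc_a: Encoder, enc_b: Encoder, dec_a: Decoder, dec_b: Decoder):
        self.enc_a = enc_a
        self.enc_b = enc_b
        self.dec_a = dec_a
        self.dec_b = dec_b

    def encode(self, x, domain: str) -> Tensor:
        enc = {"a": self.enc_a, "b": self.enc_b}[domain]
        return enc(as_tensor(x))

    def decode(self, z, domain: str) -> Tensor:
        dec = {"a": self.dec_a, "b": self.dec_b}[domain]
        return dec(as_tensor(z))

    def translate(self, x, direction: str) -> Tensor:
        if direction == "a2b":
            return self.dec_b(self.enc_a(as_tensor(x)))
        if direction == "b2a":
            return self.dec_a(self.enc_b(as_tensor(x)))
        raise ValueError(f"direction must be 'a2b' or 'b2a', got {direction!r}")


class Discriminator(Module):
    """Patch least-squares critic: strided 4×4 convs -> single-channel score map.

    Scores are unbounded reals (no sigmoid), as the least-squares objective
    requires.  Batch norm follows every strided conv except the first, the
    usual patch-critic convention.
    """

    def __init__(self, in_channels: int, channels=(64, 128, 256, 512),
                 use_batchnorm: bool = True, rng: np.random.Generator = None):
        self.convs = []
        self.bns = []
        c = in_channels
        for i, width in enumerate(channels):
            self.convs.append(Conv2d(c, width, 4, stride=2, padding=1, rng=rng))
            self.bns.append(BatchNorm2d(width) if (use_batchnorm and i > 0) else None)
            c = width
        self.head = Conv2d(c, 1, 3, padding=1, rng=rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        for conv, bn in zip(self.convs, self.bns):
            x = conv(x)
            if bn is not None:
                x = bn(x)
            x = x.leaky_relu(0.2)
        return self.head(x)
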