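"""Data pipeline and optimization loop.

One iteration = one random patch per domain, forward through both translation
directions and both cycles, a discriminator step and a generator step, both
AdamW (lr 3e-4, no weight decay, batch size 1).  Everything is seeded: the
global seed splits into independent streams for initialization, patch
sampling and augmentation, so toggling augmentation does not shift the
initialization and two runs with the same seed produce identical loss logs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from ._tensor import Tensor
from .networks import Decoder, DecoderSpec, Discriminator, Encoder, EncoderSpec, GeneratorPair
from .nn import AdamW
from .objectives import (CycleSchedule, LossWeights, adversarial_loss, cycle_loss,
                         cycle_weight, info_loss)

__all__ = [
    "TaskConfig",
    "TrainingDivergedError",
    "percentile_normalize",
    "sample_patch",
    "augment",
    "dihedral",
    "dihedral_inverse",
    "pad_to_multiple",
    "build_models",
    "train",
    "TrainResult",
]


class TrainingDivergedError(RuntimeError):
    """Raised when a loss goes non-finite; carries a diagnostic snapshot."""

    def __init__(self, message, snapshot=None):
        super().__init__(message)
        self.snapshot = snapshot or {}


@dataclass
class TaskConfig:
    """Everything needed to reproduce a training run for one task."""

    name: str = "synthetic"
    patch_size: int = 64
    norm_mode: str = "percentile"  # "percentile" | "percentile_scale" | "range01" | "none"
    norm_lo: float = 0.1
    norm_hi: float = 99.9
    levels: tuple = (8, 16, 32)
    feature_channels: int = 8
    in_channels_a: int = 1
    in_channels_b: int = 1
    use_batchnorm: bool = False
    use_modulation: bool = True
    upsampler: str = "dynamic"  # "dynamic" | "bilinear" (ablation)
    use_info_loss: bool = True  # ablation toggle
    final_activation: str = "none"
    lambda_adv: float = 1.0
    lambda_cyc: float = 5.0
    lambda_info: float = 10.0
    schedule_enabled: bool = True
    schedule_steepness: float = 10.0
    schedule_midpoint: float = 0.5
    iterations: int = 500
    learning_rate: float = 3e-4
    disc_channels: tuple = (16, 32, 64)
    augment: bool = True
    checkpoint_every: int = 100
    seed: int = 0

    def __post_init__(self):
        self.levels = tuple(self.levels)
        self.disc_channels = tuple(self.disc_channels)
        if not 0 <= self.norm_lo < self.norm_hi <= 100:
            raise ValueError("normalization percentiles need 0 <= lo < hi <= 100")
        factor = 2 ** (len(self.levels) - 1)
        if self.patch_size % factor:
            raise ValueError(
                f"patch size {self.patch_size} not divisible by 2^(levels-1)={factor}"
            )

    # ------------------------------------------------------------------ io
    def to_yaml(self) -> str:
        d = asdict(self)
        d["levels"] = list(self.levels)
        d["disc_channels"] = list(self.disc_channels)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskConfig":
        data = yaml.safe_load(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "TaskConfig":
        return cls.from_yaml(Path(path).read_text())

    @classmethod
    def from_name(cls, name: str) -> "TaskConfig":
        """Load one of the shipped per-task configs (e.g. 'calcium', 'synthetic')."""
        from importlib import resources

        ref = resources.files("stable") / "configs" / f"{name}.yaml"
        try:
            return cls.from_yaml(ref.read_text())
        except FileNotFoundError:
            avail = sorted(p.name[:-5] for p in (resources.files("stable") / "configs").iterdir())
            raise ValueError(f"no shipped config named {name!r}; available: {avail}")

    @property
    def loss_weights(self) -> LossWeights:
        return LossWeights(self.lambda_adv, self.lambda_cyc, self.lambda_info)

    def schedule(self) -> CycleSchedule:
        return CycleSchedule(self.iterations, self.schedule_steepness,
                             self.schedule_midpoint, self.schedule_enabled)


# --------------------------------------------------------------- data pipeline
def percentile_normalize(image: np.ndarray, lo: float = 0.1, hi: float = 99.9,
                         mode: str = "percentile") -> np.ndarray:
    """Normalize one image by its own intensity percentiles.

    ``"percentile"``: affine (x − P_lo)/(P_hi − P_lo).
    ``"percentile_scale"``: x / P_hi (the calcium recipe; preserves zero).
    ``"range01"``: min–max to [0, 1].  Constant images map to all zeros.
    """
    x = np.asarray(image, dtype=np.float32)
    if not np.all(np.isfinite(x)):
        raise ValueError("image contains non-finite values")
    if mode == "none":
        return x.copy()
    if mode == "range01":
        p_lo, p_hi = float(x.min()), float(x.max())
    else:
        p_lo = float(np.percentile(x, lo))
        p_hi = float(np.percentile(x, hi))
    if mode == "percentile_scale":
        if p_hi == 0.0:
            return np.zeros_like(x)
        return x / p_hi
    if p_hi == p_lo:
        return np.zeros_like(x)
    return (x - p_lo) / (p_hi - p_lo)


def sample_patch(stack: np.ndarray, patch_hw: tuple, rng) -> np.ndarray:
    """Uniformly random frame + top-left corner from a ``(T, H, W)`` stack."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    t_len, h, w = stack.shape
    ph, pw = patch_hw
    if h < ph or w < pw:
        raise ValueError(f"stack frames {h}x{w} smaller than patch {ph}x{pw}")
    t = int(rng.integers(0, t_len))
    r = int(rng.integers(0, h - ph + 1))
    c = int(rng.integers(0, w - pw + 1))
    return stack[t, r : r + ph, c : c + pw]


def dihedral(image: np.ndarray, k: int, flip_h: bool, flip_v: bool) -> np.ndarray:
    """Apply k·90° rotation then optional horizontal/vertical flips."""
    out = np.rot90(image, k, axes=(-2, -1))
    if flip_h:
        out = out[..., ::-1]
    if flip_v:
        out = out[..., ::-1, :]
    return np.ascontiguousarray(out)


def dihedral_inverse(image: np.ndarray, k: int, flip_h: bool, flip_v: bool) -> np.ndarray:
    """Inverse of :func:`dihedral` with the same parameters."""
    out = image
    if flip_v:
        out = out[..., ::-1, :]
    if flip_h:
        out = out[..., ::-1]
    return np.ascontiguousarray(np.rot90(out, -k, axes=(-2, -1)))


def augment(image: np.ndarray, rng, return_params: bool = False):
    """Random 90° rotation and independent horizontal/vertical flips."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = int(rng.integers(0, 4))
    flip_h = bool(rng.integers(0, 2))
    flip_v = bool(rng.integers(0, 2))
    out = dihedral(image, k, flip_h, flip_v)
    if return_params:
        return out, (k, flip_h, flip_v)
    return out


def pad_to_multiple(image: np.ndarray, multiple: int):
    """Reflect-pad the trailing two axes up to a multiple; returns (padded, crop)."""
    h, w = image.shape[-2:]
    ph = (-h) % multiple
    pw = (-w) % multiple
    pad = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
    out = np.pad(image, pad, mode="reflect") if (ph or pw) else image
    crop = (slice(0, h), slice(0, w))
    return out, crop


# -------------------------------------------------------------------- training
def build_models(config: TaskConfig, rng: np.random.Generator = None):
    """Instantiate the generator pair and both discriminators from a config."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    enc_a = Encoder(EncoderSpec(config.in_channels_a, config.levels,
                                config.feature_channels, config.use_batchnorm,
                                config.use_modulation, config.upsampler), rng)
    enc_b = Encoder(EncoderSpec(config.in_channels_b, config.levels,
                                config.feature_channels, config.use_batchnorm,
                                config.use_modulation, config.upsampler), rng)
    dec_a = Decoder(DecoderSpec(config.in_channels_a, config.levels,
                                config.feature_channels, config.use_batchnorm,
                                config.use_modulation, config.upsampler,
                                config.final_activation), rng)
    dec_b = Decoder(DecoderSpec(config.in_channels_b, config.levels,
                                config.feature_channels, config.use_batchnorm,
                                config.use_modulation, config.upsampler,
                                config.final_activation), rng)
    gen = GeneratorPair(enc_a, enc_b, dec_a, dec_b)
    d_a = Discriminator(config.in_channels_a, config.disc_channels,
                        config.use_batchnorm, rng)
    d_b = Discriminator(config.in_channels_b, config.disc_channels,
                        config.use_batchnorm, rng)
    return gen, d_a, d_b


@dataclass
class TrainResult:
    generators: GeneratorPair
    disc_a: Discriminator
    disc_b: Discriminator
    log: list
    config: TaskConfig


def normalize_stack(stack: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Per-frame percentile normalization (computed on full frames, pre-patch)."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    return np.stack([
        percentile_normalize(f, config.norm_lo, config.norm_hi, config.norm_mode)
        for f in stack
    ])


def train(config: TaskConfig, dataset_a: np.ndarray, dataset_b: np.ndarray,
          out_dir=None, log_every: int = 1) -> TrainResult:
    """Run the unpaired training loop on two image stacks ``(N, H, W)``.

    Discriminators are updated first (on detached translations), then the
    generators, once each per iteration.  Returns the trained models and the
    per-iteration loss log; when ``out_dir`` is given, writes a JSONL log and
    periodic checkpoints (last 3 plus best-by-generator-loss).
    """
    import json

    from .io import save_checkpoint

    ss = np.random.SeedSequence(config.seed)
    s_init, s_data, s_aug = ss.spawn(3)
    rng_init = np.random.default_rng(s_init)
    rng_data = np.random.default_rng(s_data)
    rng_aug = np.random.default_rng(s_aug)

    a = normalize_stack(dataset_a, config)
    b = normalize_stack(dataset_b, config)

    gen, d_a, d_b = build_models(config, rng_init)
    g_params = gen.parameters()
    d_params = d_a.parameters() + d_b.parameters()
    opt_g = AdamW(g_params, lr=config.learning_rate)
    opt_d = AdamW(d_params, lr=config.learning_rate)
    weights = config.loss_weights
    schedule = config.schedule()
    patch = (config.patch_size, config.patch_size)

    out_path = Path(out_dir) if out_dir is not None else None
    log_file = None
    ckpt_dir = None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        log_file = open(out_path / "training_log.jsonl", "w")
        ckpt_dir = out_path / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
    kept_ckpts: list = []
    best_loss = math.inf

    log: list = []
    try:
        for it in range(config.iterations):
            xa_np = sample_patch(a, patch, rng_data)[None]
            xb_np = sample_patch(b, patch, rng_data)[None]
            if config.augment:
                xa_np = augment(xa_np, rng_aug)
                xb_np = augment(xb_np, rng_aug)
            xa = Tensor(np.ascontiguousarray(xa_np, dtype=np.float32))
            xb = Tensor(np.ascontiguousarray(xb_np, dtype=np.float32))

            # forward translations
            za = gen.enc_a(xa)
            xab = gen.dec_b(za)
            zb = gen.enc_b(xb)
            xba = gen.dec_a(zb)

            # discriminator step (detached fakes), then generator step
            gen_adv, disc_term = adversarial_loss(d_a, d_b, xa, xb, xab, xba)
            opt_d.zero_grad()
            disc_term.backward()
            opt_d.step()

            # cycle + info paths reuse the live translation graph
            zab = gen.enc_b(xab)
            zba = gen.enc_a(xba)
            xaba = gen.dec_a(zab)
            xbab = gen.dec_b(zba)
            l_cyc = cycle_loss(xa, xb, xaba, xbab)
            lam_cyc = cycle_weight(schedule, it, config.lambda_cyc)
            if config.use_info_loss:
                # consistency-target convention: the plain encodings are
                # detached so the constraint pulls the re-encoded features
                # toward them, not both toward a degenerate constant map
                l_info = info_loss(za.detach(), zb.detach(), zab, zba)
            else:
                l_info = Tensor(np.float32(0.0))
            g_total = (weights.adv * gen_adv + lam_cyc * l_cyc
                       + weights.info * l_info)
            opt_g.zero_grad()
            for p in d_params:
                p.grad = None  # generator backward also reaches the critics
            g_total.backward()
            opt_g.step()

            row = {
                "iteration": it,
                "loss_disc": float(disc_term.item()),
                "loss_gen_total": float(g_total.item()),
                "loss_adv": float(gen_adv.item()),
                "loss_cyc": float(l_cyc.item()),
                "loss_info": float(l_info.item()),
                "cycle_weight": lam_cyc,
            }
            if not all(math.isfinite(v) for v in row.values()):
                snap = {"iteration": it, "row": row}
                if out_path is not None:
                    (out_path / "diverged.json").write_text(json.dumps(snap))
                raise TrainingDivergedError(f"non-finite loss at iteration {it}", snap)
            if it % log_every == 0 or it == config.iterations - 1:
                log.append(row)
                if log_file is not None:
                    log_file.write(json.dumps(row) + "\n")

            if ckpt_dir is not None and (
                (it + 1) % config.checkpoint_every == 0 or it == config.iterations - 1
            ):
                path = ckpt_dir / f"iter_{it + 1:06d}.npz"
                save_checkpoint(path, gen, d_a, d_b, config, iteration=it + 1)
                kept_ckpts.append(path)
                if row["loss_gen_total"] < best_loss:
                    best_loss = row["loss_gen_total"]
                    save_checkpoint(ckpt_dir / "best.npz", gen, d_a, d_b, config,
                                    iteration=it + 1)
                while len(kept_ckpts) > 3:
                    old = kept_ckpts.pop(0)
                    old.unlink(missing_ok=True)
    finally:
        if log_file is not None:
            log_file.close()
    return TrainResult(gen, d_a, d_b, log, config)
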