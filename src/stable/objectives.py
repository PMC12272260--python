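"""Training objectives: adversarial, cycle- and information-consistency losses.

The total objective is a weighted sum

    L_tot = λ_adv · L_adv + λ_cyc · L_cyc + λ_info · L_info

where L_cyc penalizes the L1 error of the round-trip reconstruction
(A→B→A and B→A→B) and L_info penalizes the L1 distance between the
full-resolution feature map of an input and the feature map re-encoded from
its translation.  L1 terms are *means* over elements so the λ values stay
comparable across patch sizes and channel counts.

The adversarial objective is the least-squares (LSGAN) form; the logistic
(cross-entropy) form is available behind ``form="logistic"`` for the record.
The cycle weight can follow a sigmoid growth schedule over training, which
stabilizes the early iterations where reconstructions are meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._tensor import Tensor, as_tensor

__all__ = [
    "LossWeights",
    "CycleSchedule",
    "adversarial_loss",
    "cycle_loss",
    "info_loss",
    "total_loss",
    "cycle_weight",
]


@dataclass(frozen=True)
class LossWeights:
    adv: float = 1.0
    cyc: float = 5.0
    info: float = 10.0

    def __post_init__(self):
        for name in ("adv", "cyc", "info"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"loss weight {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class CycleSchedule:
    """Sigmoid growth of the cycle weight: λ·σ(k·(i/I − m))."""

    total_iterations: int = 1
    steepness: float = 10.0
    midpoint: float = 0.5
    enabled: bool = True

    def __post_init__(self):
        if self.total_iterations < 1:
            raise ValueError("total_iterations must be >= 1")
        if self.steepness <= 0:
            raise ValueError("steepness must be > 0")
        if not 0.0 <= self.midpoint <= 1.0:
            raise ValueError("midpoint must be in [0, 1]")


def _mean_sq(x: Tensor) -> Tensor:
    return (x * x).mean()


def adversarial_loss(d_a, d_b, x_a, x_b, x_ab, x_ba, form: str = "lsgan"):
    """Least-squares adversarial terms for both domains.

    Returns ``(generator_term, discriminator_term)``.  The discriminator term
    scores real images against 1 and *detached* translations against 0:
    ``½·mean[(D(real)−1)²] + ½·mean[D(fake)²]`` summed over domains.  The
    generator term scores the live translations against 1:
    ``½·mean[(D(fake)−1)²]`` summed over domains.
    """
    x_ab = as_tensor(x_ab)
    x_ba = as_tensor(x_ba)
    if form == "lsgan":
        d_real_a = d_a(as_tensor(x_a))
        d_real_b = d_b(as_tensor(x_b))
        d_fake_a = d_a(x_ba.detach())
        d_fake_b = d_b(x_ab.detach())
        disc = (
            0.5 * _mean_sq(d_real_a - 1.0) + 0.5 * _mean_sq(d_fake_a)
            + 0.5 * _mean_sq(d_real_b - 1.0) + 0.5 * _mean_sq(d_fake_b)
        )
        g_fake_a = d_a(x_ba)
        g_fake_b = d_b(x_ab)
        gen = 0.5 * _mean_sq(g_fake_a - 1.0) + 0.5 * _mean_sq(g_fake_b - 1.0)
        return gen, disc
    if form == "logistic":
        # cross-entropy form on sigmoid-squashed scores
        def bce(score: Tensor, target: float) -> Tensor:
            p = score.sigmoid()
            eps = 1e-7
            if target == 1.0:
                return -((p + eps).log()).mean()
            return -(((1.0 - p) + eps).log()).mean()

        disc = (
            bce(d_a(as_tensor(x_a)), 1.0) + bce(d_a(x_ba.detach()), 0.0)
            + bce(d_b(as_tensor(x_b)), 1.0) + bce(d_b(x_ab.detach()), 0.0)
        )
        gen = bce(d_a(x_ba), 1.0) + bce(d_b(x_ab), 1.0)
        return gen, disc
    raise ValueError(f"unknown adversarial form {form!r}")


def cycle_loss(x_a, x_b, x_aba, x_bab) -> Tensor:
    """Mean-L1 round-trip reconstruction error, summed over both directions."""
    x_a, x_b = as_tensor(x_a), as_tensor(x_b)
    x_aba, x_bab = as_tensor(x_aba), as_tensor(x_bab)
    if x_a.shape != x_aba.shape or x_b.shape != x_bab.shape:
        raise ValueError("cycle_loss: reconstruction shape does not match input")
    return (x_a - x_aba).abs().mean() + (x_b - x_bab).abs().mean()


def info_loss(z_a, z_b, z_ab, z_ba) -> Tensor:
    """Mean-L1 feature-consistency error: |Z_A − G_B(X_A→B)| + |Z_B − G_A(X_B→A)|."""
    z_a, z_b = as_tensor(z_a), as_tensor(z_b)
    z_ab, z_ba = as_tensor(z_ab), as_tensor(z_ba)
    if z_a.shape != z_ab.shape or z_b.shape != z_ba.shape:
        raise ValueError("info_loss: feature map shapes do not match")
    return (z_a - z_ab).abs().mean() + (z_b - z_ba).abs().mean()


def total_loss(weights: LossWeights, l_adv, l_cyc, l_info):
    """Weighted sum λ_adv·L_adv + λ_cyc·L_cyc + λ_info·L_info."""
    return weights.adv * l_adv + weights.cyc * l_cyc + weights.info * l_info


def cycle_weight(schedule: CycleSchedule, iteration: int, lam_cyc: float) -> float:
    """Scheduled cycle weight λ_cyc·σ(k·(i/I − m)); constant when disabled."""
    if not schedule.enabled:
        return float(lam_cyc)
    if not 0 <= iteration <= schedule.total_iterations:
        raise ValueError("iteration outside [0, total_iterations]")
    z = schedule.steepness * (iteration / schedule.total_iterations - schedule.midpoint)
    return float(lam_cyc) / (1.0 + math.exp(-z))
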