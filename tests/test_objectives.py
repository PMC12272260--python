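"""Loss functions checked against brute-force elementwise oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stable._tensor import Tensor
from stable.objectives import (CycleSchedule, LossWeights, adversarial_loss, cycle_loss,
                               cycle_weight, info_loss, total_loss)


class ConstantCritic:
    """Stub discriminator returning a fixed score map regardless of input."""

    def __init__(self, value, shape=(1, 2, 2)):
        self.value = np.full(shape, float(value))

    def __call__(self, x):
        return Tensor(self.value.copy())


class LookupCritic:
    """Stub discriminator mapping input mean to a chosen score map."""

    def __init__(self, table):
        self.table = table  # {rounded input mean: score array}

    def __call__(self, x):
        key = round(float(np.mean(x.data)), 6)
        return Tensor(np.asarray(self.table[key], dtype=float))


def brute_mean_abs(a, b):
    total = 0.0
    for x, y in zip(np.ravel(a), np.ravel(b)):
        total += abs(x - y)
    return total / np.size(a)


@pytest.fixture()
def imgs(rng):
    return {k: rng.random((1, 4, 4)) for k in ("xa", "xb", "xab", "xba", "xaba", "xbab")}


class TestAdversarialLoss:
    def test_perfect_discriminator_zeroes_its_term(self, imgs):
        # D = 1 on real, 0 on fake
        table = {round(float(np.mean(imgs[k])), 6): np.ones((1, 2, 2)) for k in ("xa", "xb")}
        table.update({round(float(np.mean(imgs[k])), 6): np.zeros((1, 2, 2))
                      for k in ("xab", "xba")})
        d = LookupCritic(table)
        gen, disc = adversarial_loss(d, d, imgs["xa"], imgs["xb"], imgs["xab"], imgs["xba"])
        assert disc.item() == pytest.approx(0.0, abs=1e-12)

    def test_fooled_discriminator_zeroes_generator_term(self, imgs):
        d = ConstantCritic(1.0)
        gen, _ = adversarial_loss(d, d, imgs["xa"], imgs["xb"], imgs["xab"], imgs["xba"])
        assert gen.item() == pytest.approx(0.0, abs=1e-12)

    def test_half_constant_discriminator_quarter_per_domain(self, imgs):
        d = ConstantCritic(0.5)
        _, disc = adversarial_loss(d, d, imgs["xa"], imgs["xb"], imgs["xab"], imgs["xba"])
        # per domain: 0.5*(0.5-1)^2 + 0.5*0.5^2 = 0.25; two domains -> 0.5
        assert disc.item() == pytest.approx(0.5, abs=1e-12)

    def test_lsgan_matches_brute_force(self, rng, imgs):
        score_real_a = rng.normal(size=(1, 3, 3))
        score_fake_a = rng.normal(size=(1, 3, 3))
        score_real_b = rng.normal(size=(1, 3, 3))
        score_fake_b = rng.normal(size=(1, 3, 3))
        table = {
            round(float(np.mean(imgs["xa"])), 6): score_real_a,
            round(float(np.mean(imgs["xba"])), 6): score_fake_a,
            round(float(np.mean(imgs["xb"])), 6): score_real_b,
            round(float(np.mean(imgs["xab"])), 6): score_fake_b,
        }
        d = LookupCritic(table)
        gen, disc = adversarial_loss(d, d, imgs["xa"], imgs["xb"], imgs["xab"], imgs["xba"])
        exp_disc = (
            0.5 * np.mean((score_real_a - 1) ** 2) + 0.5 * np.mean(score_fake_a**2)
            + 0.5 * np.mean((score_real_b - 1) ** 2) + 0.5 * np.mean(score_fake_b**2)
        )
        exp_gen = 0.5 * np.mean((score_fake_a - 1) ** 2) + 0.5 * np.mean((score_fake_b - 1) ** 2)
        assert disc.item() == pytest.approx(exp_disc, abs=1e-6)
        assert gen.item() == pytest.approx(exp_gen, abs=1e-6)

    def test_logistic_form_available(self, imgs):
        d = ConstantCritic(0.0)
        gen, disc = adversarial_loss(d, d, imgs["xa"], imgs["xb"], imgs["xab"],
                                     imgs["xba"], form="logistic")
        # sigmoid(0) = 0.5 -> every BCE term is log(2)
        assert disc.item() == pytest.approx(4 * math.log(2), rel=1e-4)
        assert gen.item() == pytest.approx(2 * math.log(2), rel=1e-4)


class TestCycleLoss:
    def test_identity_generators_give_zero(self, imgs):
        assert cycle_loss(imgs["xa"], imgs["xb"], imgs["xa"], imgs["xb"]).item() == 0.0

    def test_constant_offset_half_per_direction(self, imgs):
        val = cycle_loss(imgs["xa"], imgs["xb"], imgs["xa"] + 0.5, imgs["xb"] + 0.5)
        assert val.item() == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_under_domain_swap(self, imgs):
        a = cycle_loss(imgs["xa"], imgs["xb"], imgs["xaba"], imgs["xbab"]).item()
        b = cycle_loss(imgs["xb"], imgs["xa"], imgs["xbab"], imgs["xaba"]).item()
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_brute_force(self, imgs):
        got = cycle_loss(imgs["xa"], imgs["xb"], imgs["xaba"], imgs["xbab"]).item()
        exp = brute_mean_abs(imgs["xa"], imgs["xaba"]) + brute_mean_abs(imgs["xb"], imgs["xbab"])
        assert got == pytest.approx(exp, abs=1e-6)

    def test_shape_mismatch_rejected(self, imgs):
        with pytest.raises(ValueError):
            cycle_loss(imgs["xa"], imgs["xb"], imgs["xa"][:, :2], imgs["xb"])


class TestInfoLoss:
    def test_perfect_reencoding_gives_zero(self, rng):
        z = rng.random((8, 4, 4))
        assert info_loss(z, z, z, z).item() == 0.0

    def test_constant_unit_difference(self, rng):
        z = rng.random((8, 4, 4))
        assert info_loss(z, z, z + 1.0, z).item() == pytest.approx(1.0, abs=1e-6)

    def test_decreases_along_interpolation_toward_target(self, rng):
        za, zb = rng.random((4, 3, 3)), rng.random((4, 3, 3))
        zab = rng.random((4, 3, 3))
        vals = [info_loss(za, zb, za + (1 - t) * (zab - za), zb).item()
                for t in np.linspace(0, 1, 7)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_brute_force(self, rng):
        za, zb, zab, zba = (rng.random((2, 4, 4)) for _ in range(4))
        exp = brute_mean_abs(za, zab) + brute_mean_abs(zb, zba)
        assert info_loss(za, zb, zab, zba).item() == pytest.approx(exp, abs=1e-6)

    def test_gradient_reaches_encoder_parameters(self, rng):
        from stable.training import TaskConfig, build_models

        cfg = TaskConfig.from_name("synthetic")
        cfg.levels = (4, 8)
        gen, _, _ = build_models(cfg, rng)
        x = Tensor(rng.random((1, 32, 32)).astype(np.float32))
        za = gen.enc_a(x)
        xab = gen.dec_b(za)
        zab = gen.enc_b(xab)
        loss = info_loss(za.detach(), za.detach(), zab, zab)
        loss.backward()
        grads = [p.grad for p in gen.enc_a.parameters() if p.grad is not None]
        assert grads and max(np.abs(g).max() for g in grads) > 0


class TestTotalLoss:
    def test_calcium_weighting_example(self):
        w = LossWeights(adv=1, cyc=5, info=10)
        assert total_loss(w, 2.0, 3.0, 4.0) == pytest.approx(57.0)

    def test_zero_weights(self):
        assert total_loss(LossWeights(0, 0, 0), 2.0, 3.0, 4.0) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0, 10),
           st.floats(0, 5), st.floats(0, 5), st.floats(0, 5))
    def test_linear_in_each_weight(self, wa, wc, wi, la, lc, li):
        w1 = LossWeights(wa, wc, wi)
        w2 = LossWeights(2 * wa, 2 * wc, 2 * wi)
        assert total_loss(w2, la, lc, li) == pytest.approx(2 * total_loss(w1, la, lc, li),
                                                           rel=1e-9, abs=1e-9)

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0, 0.0)


class TestCycleWeight:
    def test_midpoint_is_half_weight(self):
        s = CycleSchedule(total_iterations=100, steepness=10, midpoint=0.5)
        assert cycle_weight(s, 50, 6.0) == pytest.approx(3.0)

    def test_approaches_full_weight_with_steep_growth(self):
        s = CycleSchedule(total_iterations=100, steepness=50, midpoint=0.5)
        assert cycle_weight(s, 100, 5.0) == pytest.approx(5.0, abs=1e-6)

    def test_monotone_nondecreasing(self):
        s = CycleSchedule(total_iterations=200, steepness=8, midpoint=0.3)
        vals = [cycle_weight(s, i, 5.0) for i in range(0, 201, 10)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_disabled_schedule_is_constant(self):
        s = CycleSchedule(total_iterations=100, enabled=False)
        assert cycle_weight(s, 0, 7.0) == 7.0
        assert cycle_weight(s, 100, 7.0) == 7.0
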