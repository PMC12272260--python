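"""Data pipeline, task configs and the optimization loop."""

import numpy as np
import pytest
import scipy.stats

from stable.training import (TaskConfig, augment, build_models, dihedral,
                             dihedral_inverse, pad_to_multiple, percentile_normalize,
                             sample_patch, train)


class TestPercentileNormalize:
    def test_affine_endpoints(self):
        img = np.arange(101, dtype=float).reshape(1, 101)
        out = percentile_normalize(img, 0, 100, mode="percentile")
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_image_maps_to_zeros(self):
        np.testing.assert_array_equal(
            percentile_normalize(np.full((4, 4), 3.0), 0.1, 99.9), np.zeros((4, 4))
        )

    def test_scale_only_calcium_mode(self):
        img = np.arange(1000, dtype=float)
        out = percentile_normalize(img, 0, 99, mode="percentile_scale")
        # 99th percentile by linear interpolation of [0..999] is 989.01
        assert out.max() == pytest.approx(999 / 989.01, rel=1e-9)
        assert out.min() == 0.0

    def test_range01_mode(self, rng):
        img = rng.normal(5, 3, (16, 16))
        out = percentile_normalize(img, 0, 100, mode="range01")
        assert out.min() == 0.0 and out.max() == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            percentile_normalize(np.array([1.0, np.nan]), 0, 99)


class TestSamplePatch:
    def test_patch_sized_stack_returns_whole_frame(self, rng):
        stack = rng.random((3, 8, 8))
        patch = sample_patch(stack, (8, 8), rng)
        assert any(np.array_equal(patch, f) for f in stack)

    def test_same_seed_identical(self, rng):
        stack = rng.random((4, 32, 32))
        a = sample_patch(stack, (8, 8), 123)
        b = sample_patch(stack, (8, 8), 123)
        np.testing.assert_array_equal(a, b)

    def test_too_small_stack_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_patch(rng.random((1, 4, 4)), (8, 8), 0)

    def test_corner_distribution_uniform(self):
        # 4 possible corners per axis when H - ph + 1 = 4
        stack = np.zeros((1, 11, 11))
        gen = np.random.default_rng(0)
        counts = np.zeros((4, 4))
        marker = np.arange(11 * 11, dtype=float).reshape(11, 11)
        stack[0] = marker
        for _ in range(10_000):
            patch = sample_patch(stack, (8, 8), gen)
            r, c = divmod(int(patch[0, 0]), 11)
            counts[r, c] += 1
        chi2 = ((counts - 625.0) ** 2 / 625.0).sum()
        assert chi2 < scipy.stats.chi2.ppf(0.999, df=15)


class TestAugment:
    def test_identity_element_unchanged(self, rng):
        img = rng.random((16, 16))
        np.testing.assert_array_equal(dihedral(img, 0, False, False), img)

    def test_pixel_multiset_preserved(self, rng):
        img = rng.random((16, 16))
        out = augment(img, 42)
        np.testing.assert_array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_inverse_recovers_input_exactly(self, rng):
        img = rng.random((12, 12))
        for seed in range(16):
            out, params = augment(img, seed, return_params=True)
            np.testing.assert_array_equal(dihedral_inverse(out, *params), img)


class TestTaskConfig:
    @pytest.mark.parametrize("name", ["synthetic", "calcium", "he_staining", "dapi",
                                      "mri", "penicillium", "planaria"])
    def test_all_shipped_configs_load_and_roundtrip(self, name):
        cfg = TaskConfig.from_name(name)
        again = TaskConfig.from_yaml(cfg.to_yaml())
        assert again == cfg

    def test_calcium_recipe_values(self):
        cfg = TaskConfig.from_name("calcium")
        assert (cfg.lambda_adv, cfg.lambda_cyc, cfg.lambda_info) == (1.0, 5.0, 10.0)
        assert cfg.levels == (8, 16, 32) and cfg.feature_channels == 8
        assert not cfg.use_batchnorm and cfg.schedule_enabled
        assert cfg.norm_mode == "percentile_scale" and cfg.norm_hi == 99.0
        assert cfg.learning_rate == 3e-4

    def test_he_recipe_values(self):
        cfg = TaskConfig.from_name("he_staining")
        assert (cfg.lambda_adv, cfg.lambda_cyc, cfg.lambda_info) == (5.0, 10.0, 10.0)
        assert cfg.levels == (32, 64, 128, 256) and cfg.feature_channels == 3
        assert cfg.use_batchnorm and cfg.in_channels_b == 3

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(norm_lo=50, norm_hi=10)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TaskConfig(patch_size=50, levels=(8, 16, 32))

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            TaskConfig.from_yaml("name: x\nbogus_key: 1\n")


class TestPadToMultiple:
    def test_roundtrip(self, rng):
        img = rng.random((1, 30, 37))
        padded, crop = pad_to_multiple(img, 8)
        assert padded.shape == (1, 32, 40)
        np.testing.assert_array_equal(padded[(slice(None),) + crop], img)

    def test_already_divisible_untouched(self, rng):
        img = rng.random((1, 32, 32))
        padded, _ = pad_to_multiple(img, 8)
        assert padded is img


class TestTrainLoop:
    def test_smoke_ten_iterations_logs_ten_rows(self, tiny_dataset, tiny_config):
        res = train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b)
        assert len(res.log) == 10
        assert {"iteration", "loss_disc", "loss_gen_total", "loss_adv", "loss_cyc",
                "loss_info", "cycle_weight"} <= set(res.log[0])

    def test_same_seed_identical_loss_logs(self, tiny_dataset, tiny_config):
        a = train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b)
        b = train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b)
        assert a.log == b.log

    def test_ablation_toggles_respected(self, tiny_dataset, tiny_config):
        from stable.upsampling import BilinearUpsample

        tiny_config.use_info_loss = False
        tiny_config.upsampler = "bilinear"
        tiny_config.iterations = 3
        res = train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b)
        assert all(row["loss_info"] == 0.0 for row in res.log)
        assert all(isinstance(u, BilinearUpsample) for u in res.generators.enc_a.ups)

    def test_writes_log_and_checkpoints(self, tiny_dataset, tiny_config, tmp_path):
        tiny_config.iterations = 4
        tiny_config.checkpoint_every = 2
        train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b, out_dir=tmp_path)
        log_lines = (tmp_path / "training_log.jsonl").read_text().splitlines()
        assert len(log_lines) == 4
        ckpts = sorted(p.name for p in (tmp_path / "checkpoints").glob("iter_*.npz"))
        assert ckpts == ["iter_000002.npz", "iter_000004.npz"]
        assert (tmp_path / "checkpoints" / "best.npz").exists()

    def test_scheduled_cycle_weight_grows(self, tiny_dataset, tiny_config):
        tiny_config.schedule_enabled = True
        tiny_config.iterations = 6
        res = train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b)
        w = [row["cycle_weight"] for row in res.log]
        assert w == sorted(w) and w[0] < w[-1]


class TestCheckpointRoundtrip:
    def test_save_load_reproduces_outputs(self, tiny_dataset, tiny_config, tmp_path, rng):
        from stable.io import load_checkpoint, save_checkpoint

        tiny_config.iterations = 2
        res = train(tiny_config, tiny_dataset.train_a, tiny_dataset.train_b)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, res.generators, res.disc_a, res.disc_b, tiny_config, 2)
        cfg2, gen2, _, _, it = load_checkpoint(path)
        assert it == 2 and cfg2 == tiny_config
        x = rng.random((1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(res.generators.translate(x, "a2b").data,
                                      gen2.translate(x, "a2b").data)

    def test_mismatched_spec_rejected(self, tiny_dataset, tiny_config, tmp_path):
        from stable.io import save_checkpoint
        from stable.nn import Module

        gen, d_a, d_b = build_models(tiny_config)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, gen, d_a, d_b, tiny_config, 0)
        other = TaskConfig.from_name("synthetic")
        other.levels = (4, 8)
        gen2, _, _ = build_models(other)
        import numpy as _np

        state = {k: _np.asarray(v) for k, v in gen.state_dict().items()}
        with pytest.raises(ValueError, match="state dict mismatch|shape"):
            gen2.load_state_dict(state)
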