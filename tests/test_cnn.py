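"""Numpy U-Net: architecture contracts, gradients, training, probes."""

import numpy as np
import pytest

from dbarnet.cnn import (ArchitectureSpec, TrainingConfig,
                         adversarial_perturbation, build_network, garbage_test,
                         load_checkpoint, predict, save_checkpoint, train)
from dbarnet.cnn import _forward, _backward, _loss_and_grad
from dbarnet.exceptions import ConfigurationError


class TestArchitecture:
    def test_residual_with_zeroed_final_layer_is_identity(self, rng):
        spec = ArchitectureSpec(residual=True, base_channels=3)
        p = build_network(spec, seed=0, final_zero_init=True)
        x = rng.random((2, 64, 64)).astype(np.float32)
        y, _ = _forward(p, x)
        assert np.array_equal(y, x)

    @pytest.mark.parametrize("n", [64, 128])
    def test_output_shape_matches_input(self, rng, n):
        p = build_network(ArchitectureSpec(base_channels=2), seed=0)
        x = rng.random((1, n, n)).astype(np.float32)
        y, _ = _forward(p, x)
        assert y.shape == (1, n, n)

    def test_same_seed_identical_parameters(self):
        spec = ArchitectureSpec(base_channels=4)
        a = build_network(spec, seed=5)
        b = build_network(spec, seed=5)
        assert all(np.array_equal(a.weights[k], b.weights[k])
                   for k in a.weights)

    def test_indivisible_grid_rejected(self, rng):
        p = build_network(ArchitectureSpec(base_channels=2), seed=0)
        with pytest.raises(ConfigurationError):
            _forward(p, rng.random((1, 50, 50)).astype(np.float32))


class TestGradients:
    def test_weight_and_input_gradients_match_finite_differences(self):
        spec = ArchitectureSpec(residual=True, base_channels=2, pool_levels=2)
        p = build_network(spec, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((1, 16, 16)).astype(np.float32)
        t = rng.random((1, 16, 16)).astype(np.float32)
        loss, grads = _loss_and_grad(p, x, t)
        eps = 1e-3
        for key in ["enc0_W", "dec1_W", "proj0_b", "out_W"]:
            idx = tuple(0 for _ in grads[key].shape)
            p.weights[key][idx] += eps
            lp, _ = _loss_and_grad(p, x, t)
            p.weights[key][idx] -= 2 * eps
            lm, _ = _loss_and_grad(p, x, t)
            p.weights[key][idx] += eps
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grads[key][idx]) < 2e-2 * max(1.0, abs(fd)), key
        # input gradient
        pred, cache = _forward(p, x, want_cache=True)
        _, dx = _backward(p, cache, 2 * (pred - t))
        j = (0, 5, 7)
        xp = x.copy(); xp[j] += eps
        xm = x.copy(); xm[j] -= eps
        lp = float(np.sum((_forward(p, xp)[0] - t) ** 2))
        lm = float(np.sum((_forward(p, xm)[0] - t) ** 2))
        assert abs(dx[j] - (lp - lm) / (2 * eps)) < 2e-2 * max(1.0, abs(dx[j]))


class TestTraining:
    def test_identity_task_reaches_small_validation_loss(self, rng):
        x = rng.random((64, 32, 32)).astype(np.float32)
        spec = ArchitectureSpec(residual=True, base_channels=2, pool_levels=2)
        cfg = TrainingConfig(iterations=500, seed=1, checkpoint_every=100)
        p = train(x, x, spec=spec, config=cfg)
        assert p.val_loss[-1][1] < 1e-3

    def test_smoothed_training_loss_decreases(self, rng):
        # blurred-to-sharp toy task
        from scipy.ndimage import gaussian_filter
        sharp = np.zeros((64, 32, 32), dtype=np.float32)
        for i in range(64):
            c = rng.integers(8, 24, size=2)
            sharp[i, c[0] - 5:c[0] + 5, c[1] - 5:c[1] + 5] = 1.0
        blurred = np.stack([gaussian_filter(s, 2.0) for s in sharp])
        spec = ArchitectureSpec(residual=True, base_channels=2, pool_levels=2)
        p = train(blurred, sharp, spec=spec,
                  config=TrainingConfig(iterations=600, seed=0))
        head = np.mean(p.train_loss[:100])
        tail = np.mean(p.train_loss[-100:])
        assert tail < head

    def test_default_config_echoes_study_settings(self):
        cfg = TrainingConfig()
        assert cfg.batch_size == 16
        assert cfg.learning_rate == 1e-4


class TestPredict:
    def test_batch_order_preserved(self, rng):
        p = build_network(ArchitectureSpec(base_channels=2), seed=0)
        x = rng.random((5, 64, 64)).astype(np.float32)
        y = predict(p, x)
        # single-image and batched evaluation agree up to float32 BLAS
        # reduction-order differences
        for i in range(5):
            assert np.allclose(predict(p, x[i]), y[i], atol=5e-4)

    def test_positive_floor_applied(self, rng):
        p = build_network(ArchitectureSpec(base_channels=2), seed=0)
        x = rng.random((1, 64, 64)).astype(np.float32)
        assert predict(p, x, floor=1e-3).min() >= 1e-3

    def test_checkpoint_round_trip(self, tmp_path, rng):
        p = build_network(ArchitectureSpec(residual=True, base_channels=2),
                          seed=2)
        path = str(tmp_path / "ckpt.npz")
        save_checkpoint(p, path)
        q = load_checkpoint(path)
        x = rng.random((2, 64, 64)).astype(np.float32)
        assert np.array_equal(predict(p, x), predict(q, x))
        assert q.spec == p.spec


class TestRobustnessProbes:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter
        sharp = np.zeros((48, 32, 32), dtype=np.float32)
        for i in range(48):
            c = rng.integers(10, 22, size=2)
            sharp[i, c[0] - 4:c[0] + 4, c[1] - 4:c[1] + 4] = 1.0
        blurred = np.stack([gaussian_filter(s, 1.5) for s in sharp])
        spec = ArchitectureSpec(residual=True, base_channels=2, pool_levels=2)
        p = train(blurred, sharp, spec=spec,
                  config=TrainingConfig(iterations=300, seed=0))
        return p, blurred

    def test_zero_perturbation_gives_zero_objective(self, trained):
        p, x = trained
        _, trace = adversarial_perturbation(p, x[0], steps=1)
        assert trace[0] == 0.0

    def test_objective_trace_non_decreasing(self, trained):
        p, x = trained
        snaps, trace = adversarial_perturbation(p, x[0], alpha=1.0, steps=30)
        assert np.all(np.diff(trace) >= -1e-7)
        assert trace[-1] >= trace[0]
        assert len(snaps) >= 1

    def test_garbage_outputs_finite_and_deterministic(self, trained):
        p, x = trained
        lo, hi = float(x.min()), float(x.max())
        for spec_name in ("uniform", "gaussian"):
            a = garbage_test(p, spec_name, (2, 32, 32),
                             np.random.default_rng(9), input_range=(lo, hi))
            b = garbage_test(p, spec_name, (2, 32, 32),
                             np.random.default_rng(9), input_range=(lo, hi))
            assert np.all(np.isfinite(a))
            assert np.array_equal(a, b)
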