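"""Architecture contracts, loss oracles, gradients, and training behavior."""

import numpy as np
import pytest

from ahre.nnet import softmax
from ahre.resnet1d import (
    ModelSpec,
    TrainConfig,
    build_model,
    check_pretraining_pool,
    focal_loss,
    focal_loss_grad,
    fbeta,
    load_checkpoint,
    pretrain_then_transfer,
    save_checkpoint,
    stem_output_length,
    train,
    weighted_f2,
)
from ahre.episodes import Label

TINY = ModelSpec(input_length=64, input_channels=2, filters=4, hidden=8, n_classes=3)


class TestArchitecture:
    def test_stem_compresses_1280_to_320(self):
        model = build_model(ModelSpec(), seed=0)
        assert stem_output_length(model) == 320

    def test_forward_rows_on_probability_simplex(self):
        model = build_model(TINY, seed=0)
        x = np.random.default_rng(0).standard_normal((7, 64, 2))
        probs = softmax(model.forward(x))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_eval_mode_deterministic_and_batch_order_invariant(self):
        model = build_model(TINY, seed=1)
        x = np.random.default_rng(1).standard_normal((6, 64, 2)).astype(np.float32)
        p1 = model.predict_proba(x)
        p2 = model.predict_proba(x[::-1])[::-1]
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_indivisible_input_length_rejected_at_build(self):
        with pytest.raises(ValueError):
            build_model(ModelSpec(input_length=1282), seed=0)

    def test_parameter_count_deterministic(self):
        assert build_model(TINY, 0).n_parameters() == build_model(TINY, 5).n_parameters()

    def test_second_stage_downsamples_by_two(self):
        model = build_model(ModelSpec(), seed=0)
        model.forward(np.zeros((1, 1280, 2), dtype=np.float32))
        assert model.activation("block1b").shape[1] == 320
        assert model.activation("block2b").shape[1] == 160


class TestGradients:
    def test_backprop_matches_float64_finite_differences(self):
        """Full-network gradient check against a float64 numeric oracle."""
        model = build_model(TINY, seed=3)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((5, 64, 2))
        y = rng.integers(0, 3, 5)
        eye = np.eye(3)

        def loss64():
            h = x.copy()
            for _, u in model.units:
                h = u.forward(h, True)
            return focal_loss(softmax(h), eye[y], 2.0)

        logits = model.forward(x.astype(np.float32), train=True)
        model.backward(focal_loss_grad(softmax(logits), eye[y], 2.0))

        eps = 1e-5
        checked = 0
        for name, unit in model.units:
            subs = unit.sublayers if hasattr(unit, "sublayers") else [unit]
            for i, lay in enumerate(subs):
                for pname, p in lay.params.items():
                    g = lay.grads.get(pname)
                    if g is None:
                        continue
                    idx = tuple(d // 2 for d in p.shape)
                    orig = float(p[idx])
                    p[idx] = orig + eps
                    lp = loss64()
                    p[idx] = orig - eps
                    lm = loss64()
                    p[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = float(g[idx])
                    assert abs(num - ana) <= 5e-3 * max(abs(num), abs(ana), 1e-2), (
                        f"{name}.{i}.{pname}: numeric {num} vs analytic {ana}"
                    )
                    checked += 1
        assert checked > 30


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            logits = rng.normal(0, 3, (32, 3))
            probs = softmax(logits)
            y = rng.integers(0, 3, 32)
            onehot = np.eye(3)[y]
            ce = -np.mean(np.log(np.clip(probs[np.arange(32), y], 1e-7, None)))
            assert abs(focal_loss(probs, onehot, gamma=0.0) - ce) <= 1e-9

    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert focal_loss(probs, np.array([[1.0, 0.0, 0.0]]), 2.0) < 1e-12

    def test_hand_computed_batch(self):
        # p_true = (0.5, 0.9), gamma = 2 -> mean of (0.25 ln2, 0.01 ln(10/9))
        probs = np.array([[0.5, 0.3, 0.2], [0.9, 0.05, 0.05]])
        onehot = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        expected = np.mean([0.25 * np.log(2), 0.01 * np.log(10 / 9)])
        assert abs(focal_loss(probs, onehot, gamma=2.0) - expected) < 1e-12

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]), gamma=-1.0)

    def test_gradient_matches_numeric_on_logits(self):
        rng = np.random.default_rng(4)
        z = rng.normal(0, 2, (6, 3))
        y = rng.integers(0, 3, 6)
        onehot = np.eye(3)[y]
        g = focal_loss_grad(softmax(z), onehot, 2.0)
        eps = 1e-6
        for i in range(6):
            for j in range(3):
                zp, zm = z.copy(), z.copy()
                zp[i, j] += eps
                zm[i, j] -= eps
                num = (focal_loss(softmax(zp), onehot, 2.0) - focal_loss(softmax(zm), onehot, 2.0)) / (2 * eps)
                assert abs(num - g[i, j]) < 1e-6


class TestWeightedF2:
    def test_fbeta_closed_form(self):
        assert abs(fbeta(0.5, 1.0, 2.0) - 5 / 6) < 1e-12

    def test_uniform_performance_is_identity(self):
        # all classes P=R=0.8 -> weighted F2 = 0.8
        y_true = np.repeat([0, 1, 2], 10)
        y_pred = y_true.copy()
        # corrupt 2 of each class symmetrically: P=R=0.8 per class
        y_pred[[0, 1]] = [1, 2]
        y_pred[[10, 11]] = [2, 0]
        y_pred[[20, 21]] = [0, 1]
        assert abs(weighted_f2(y_true, y_pred, 3) - 0.8) < 1e-12

    def test_single_class_equals_that_f2(self):
        y_true = np.zeros(10, dtype=int)
        y_pred = np.array([0] * 8 + [1] * 2)
        # recall 0.8, precision 1.0 -> F2 = 5*0.8/(4+0.8)
        assert abs(weighted_f2(y_true, y_pred, 3) - fbeta(1.0, 0.8)) < 1e-12


class TestTransferAndTraining:
    def _toy(self, n, seed, n_classes=2):
        """Amplitude-coded separable toy on the tiny input length."""
        rng = np.random.default_rng(seed)
        t = np.arange(64) / 64
        x = np.zeros((n, 64, 2), dtype=np.float32)
        y = rng.integers(0, n_classes, n)
        for i in range(n):
            amp = 0.25 + 0.5 * y[i] / max(n_classes - 1, 1)
            x[i, :, 0] = amp * np.sin(2 * np.pi * 8 * t + rng.uniform(0, 6.28))
            x[i, :, 1] = amp * np.cos(2 * np.pi * 4 * t + rng.uniform(0, 6.28))
            x[i] += rng.normal(0, 0.02, (64, 2))
        return x, y

    def test_transfer_copies_all_but_final_dense(self):
        pre = build_model(ModelSpec(input_length=64, filters=4, hidden=8, n_classes=2), seed=0)
        post = pretrain_then_transfer(pre, n_classes=3, seed=9)
        s_pre, s_post = pre.state_dict(), post.state_dict()
        for key in s_pre:
            if key.startswith("fc_out"):
                continue
            np.testing.assert_array_equal(s_pre[key], s_post[key])
        assert s_post["fc_out.0.W"].shape == (8, 3)
        assert s_pre["fc_out.0.W"].shape == (8, 2)
        probs = post.predict_proba(np.zeros((2, 64, 2), dtype=np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_pretraining_pool_guard(self):
        with pytest.raises(ValueError):
            check_pretraining_pool([Label.SINUS, Label.ATAF, Label.NOISE])
        check_pretraining_pool([Label.SINUS, Label.ATAF])  # ok

    def test_learnable_toy_reaches_f2_095_and_respects_schedule(self):
        x, y = self._toy(240, seed=0)
        xv, yv = self._toy(80, seed=1)
        model = build_model(ModelSpec(input_length=64, filters=4, hidden=8, n_classes=2), seed=2)
        cfg = TrainConfig(max_epochs=50, patience=5, seed=3)
        res = train(model, x, y, xv, yv, cfg)
        assert res.best_f2 >= 0.95
        assert len(res.history) <= 50
        # early stopping: no more than patience epochs after the best one
        assert len(res.history) <= res.best_epoch + cfg.patience

    def test_empty_split_rejected(self):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, np.zeros((0, 64, 2)), np.zeros(0, int), np.zeros((1, 64, 2)), np.zeros(1, int), TrainConfig())

    def test_training_reproducible_under_fixed_seed(self):
        x, y = self._toy(60, seed=5)
        xv, yv = self._toy(20, seed=6)
        hists = []
        for _ in range(2):
            model = build_model(ModelSpec(input_length=64, filters=4, hidden=8, n_classes=2), seed=7)
            res = train(model, x, y, xv, yv, TrainConfig(max_epochs=3, seed=8))
            hists.append(res.history)
        assert hists[0].equals(hists[1])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_model(TINY, seed=0)
        x = np.random.default_rng(2).standard_normal((4, 64, 2)).astype(np.float32)
        before = model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, seed=42)
        after = load_checkpoint(path).predict_proba(x)
        np.testing.assert_allclose(before, after, atol=1e-7)
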