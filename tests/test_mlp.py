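import json

import numpy as np
import pytest
from sklearn.model_selection import KFold

from sclimagery import (TrainConfig, evaluate, forward, kfold_split, predict,
                        train_ensemble, train_fold)
from sclimagery.mlp import (AdamState, EnsembleModel, FoldModel, MLPWeights,
                            adam_step, ensemble_from_dict, ensemble_to_dict,
                            ensemble_weights_from_losses, gradient, init_weights,
                            mse)


def random_weights(seed):
    return init_weights(seed)


def finite_difference_gradient(w, X, y, eps=1e-5):
    """Central-difference oracle for the MSE gradient."""
    grads = []
    for p in w.params():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            hi = mse(w, X, y)
            p[idx] = orig - eps
            lo = mse(w, X, y)
            p[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads


class TestInitWeights:
    def test_deterministic_per_seed(self):
        a, b = init_weights(3), init_weights(3)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)

    def test_zeros_scheme(self):
        w = init_weights(0, scheme="zeros")
        assert all(np.all(p == 0) for p in w.params())

    def test_entries_within_glorot_bounds(self):
        w = init_weights(11)
        for W, (fan_out, fan_in) in zip((w.W1, w.W2, w.W3),
                                        ((7, 3), (9, 7), (1, 9))):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            assert np.all(np.abs(W) <= bound)

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            MLPWeights(np.zeros((7, 4)), np.zeros(7), np.zeros((9, 7)),
                       np.zeros(9), np.zeros((1, 9)), np.zeros(1))


class TestForward:
    def test_all_zero_weights_give_output_bias(self):
        w = init_weights(0, scheme="zeros")
        w.b3[0] = 2.5
        assert forward(w, [0.3, -0.1, 0.9]) == pytest.approx(2.5)

    def test_matches_independent_matrix_arithmetic(self):
        w = random_weights(4)
        x = np.array([0.2, -0.7, 0.5])
        h1 = np.tanh(w.W1 @ x + w.b1)
        h2 = np.tanh(w.W2 @ h1 + w.b2)
        expected = float((w.W3 @ h2 + w.b3)[0])
        assert forward(w, x) == pytest.approx(expected, rel=1e-12)

    def test_zeroed_input_column_makes_input_irrelevant(self):
        w = random_weights(5)
        w.W1[:, 2] = 0.0
        a = forward(w, [0.1, 0.2, -0.9])
        b = forward(w, [0.1, 0.2, 0.9])
        assert a == pytest.approx(b)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            forward(random_weights(0), [0.1, 0.2])


class TestGradient:
    def test_perfect_predictions_give_zero_gradient(self):
        w = random_weights(6)
        X = np.random.default_rng(0).uniform(-1, 1, size=(5, 3))
        y = forward(w, X)
        grads = gradient(w, X, y)
        assert all(np.allclose(g, 0.0, atol=1e-12) for g in grads)

    def test_duplicated_batch_has_same_gradient(self):
        w = random_weights(7)
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(4, 3))
        y = rng.normal(size=4)
        g1 = gradient(w, X, y)
        g2 = gradient(w, np.vstack([X, X]), np.concatenate([y, y]))
        assert all(np.allclose(a, b, atol=1e-12) for a, b in zip(g1, g2))

    def test_empty_batch_is_error(self):
        with pytest.raises(ValueError):
            gradient(random_weights(0), np.empty((0, 3)), np.empty(0))

    def test_matches_finite_differences_on_random_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            w = init_weights(int(rng.integers(2 ** 31)))
            X = rng.uniform(-1, 1, size=(6, 3))
            y = rng.normal(scale=3.0, size=6)
            analytic = gradient(w, X, y)
            numeric = finite_difference_gradient(w, X, y)
            for ga, gn in zip(analytic, numeric):
                denom = np.linalg.norm(ga) + np.linalg.norm(gn) + 1e-12
                assert np.linalg.norm(ga - gn) / denom < 1e-6


class TestAdam:
    def test_zero_gradient_leaves_weights_unchanged(self):
        w = random_weights(8)
        before = [p.copy() for p in w.params()]
        state = AdamState.for_weights(w)
        zero = [np.zeros_like(p) for p in w.params()]
        for _ in range(5):
            adam_step(w, state, zero, TrainConfig())
        assert all(np.array_equal(a, b) for a, b in zip(before, w.params()))

    def test_first_step_is_lr_times_sign(self):
        w = init_weights(0, scheme="zeros")
        state = AdamState.for_weights(w)
        grads = [np.full_like(p, 0.5) for p in w.params()]
        cfg = TrainConfig(learning_rate=1e-3)
        adam_step(w, state, grads, cfg)
        for p in w.params():
            assert np.allclose(p, -1e-3, rtol=1e-4)

    def test_converges_on_scalar_quadratic(self):
        # minimize (theta - 2)^2 using the same update rule
        theta = np.zeros(1)
        state_m, state_v = np.zeros(1), np.zeros(1)
        cfg = TrainConfig(learning_rate=0.05)
        for t in range(1, 2001):
            g = 2 * (theta - 2.0)
            state_m = cfg.beta1 * state_m + (1 - cfg.beta1) * g
            state_v = cfg.beta2 * state_v + (1 - cfg.beta2) * g ** 2
            mhat = state_m / (1 - cfg.beta1 ** t)
            vhat = state_v / (1 - cfg.beta2 ** t)
            theta -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)
        assert theta[0] == pytest.approx(2.0, abs=1e-3)


class TestKFold:
    def test_study_geometry_30_by_10(self):
        sets = kfold_split(30, 10, seed=0)
        assert len(sets) == 10
        assert all(s.size == 3 for s in sets)
        union = np.concatenate(sets)
        assert sorted(union) == list(range(30))

    def test_partition_property(self):
        sets = kfold_split(23, 5, seed=1)
        union = np.concatenate(sets)
        assert len(union) == len(set(union)) == 23

    def test_balanced_remainder(self):
        sizes = sorted(s.size for s in kfold_split(10, 3, seed=2))
        assert sizes == [3, 3, 4]

    def test_sizes_match_sklearn_convention(self):
        ours = sorted(s.size for s in kfold_split(17, 4, seed=3))
        sk = sorted(len(val) for _, val in KFold(n_splits=4, shuffle=True,
                                                 random_state=0).split(range(17)))
        assert ours == sk


def linear_rows(n, seed, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, 3))
    y = 1.0 + 2.0 * X[:, 0] - 1.5 * X[:, 1] + 0.5 * X[:, 2]
    if noise:
        y = y + rng.normal(scale=noise, size=n)
    return X, y


class TestTraining:
    def test_noiseless_linear_data_is_fit_closely(self):
        X, y = linear_rows(60, seed=0)
        fold = train_fold(X[:48], y[:48], X[48:], y[48:],
                          TrainConfig(max_epochs=8000, patience=400), seed=1)
        assert fold.val_loss < 0.05

    def test_early_stopping_restores_best_weights(self):
        X, y = linear_rows(40, seed=1, noise=0.5)
        cfg = TrainConfig(max_epochs=50, patience=1)
        fold = train_fold(X[:30], y[:30], X[30:], y[30:], cfg, seed=2)
        assert fold.epochs_run <= 50
        # returned weights achieve the recorded best validation loss
        from sclimagery.mlp import rmse_of
        assert rmse_of(fold.weights, X[30:], y[30:]) == pytest.approx(fold.val_loss)

    def test_training_is_deterministic(self):
        X, y = linear_rows(30, seed=2, noise=0.3)
        cfg = TrainConfig(max_epochs=300, patience=30, k=5, seed=9)
        a = train_ensemble(X, y, cfg)
        b = train_ensemble(X, y, cfg)
        assert np.array_equal(a.ensemble_weights, b.ensemble_weights)
        for fa, fb in zip(a.folds, b.folds):
            assert fa.val_loss == fb.val_loss
            assert all(np.array_equal(pa, pb) for pa, pb
                       in zip(fa.weights.params(), fb.weights.params()))


class TestEnsemble:
    def test_inverse_loss_weights(self):
        assert np.allclose(ensemble_weights_from_losses([1.0, 3.0]), [0.75, 0.25])
        assert np.allclose(ensemble_weights_from_losses([2.0, 2.0, 2.0, 2.0]),
                           0.25)

    def test_weights_form_probability_vector(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            w = ensemble_weights_from_losses(rng.uniform(0.01, 10, size=10))
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0)

    def test_zero_loss_guarded(self):
        w = ensemble_weights_from_losses([0.0, 1.0])
        assert w.sum() == pytest.approx(1.0)
        assert w[0] > 0.99

    def test_single_fold_prediction_equals_forward(self):
        weights = init_weights(1)
        ens = EnsembleModel(folds=[FoldModel(weights, 0.5, 10)],
                            ensemble_weights=np.array([1.0]),
                            config=TrainConfig())
        x = [0.1, -0.4, 0.8]
        assert predict(ens, x) == pytest.approx(forward(weights, x))

    def test_prediction_is_convex_combination_of_folds(self):
        folds = [FoldModel(init_weights(s), 1.0 + s, 5) for s in range(3)]
        ens = EnsembleModel(folds=folds,
                            ensemble_weights=ensemble_weights_from_losses(
                                [f.val_loss for f in folds]),
                            config=TrainConfig())
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, size=(20, 3))
        per_fold = np.stack([forward(f.weights, X) for f in folds])
        pred = predict(ens, X)
        assert np.all(pred >= per_fold.min(axis=0) - 1e-12)
        assert np.all(pred <= per_fold.max(axis=0) + 1e-12)
        # and matches the hand-computed weighted mean
        assert np.allclose(pred, ens.ensemble_weights @ per_fold)


class TestEvaluate:
    def test_perfect_predictions(self):
        w = init_weights(2)
        ens = EnsembleModel([FoldModel(w, 0.1, 1)], np.array([1.0]), TrainConfig())
        X = np.random.default_rng(5).uniform(-1, 1, size=(10, 3))
        y = forward(w, X)
        m = evaluate(ens, X, y)
        assert m.rmse == pytest.approx(0.0, abs=1e-12)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_predictor_at_mean_has_zero_r2(self):
        w = init_weights(0, scheme="zeros")
        ens = EnsembleModel([FoldModel(w, 0.1, 1)], np.array([1.0]), TrainConfig())
        X = np.zeros((6, 3))
        y = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])  # mean 0 = model output
        assert evaluate(ens, X, y).r2 == pytest.approx(0.0)

    def test_matches_brute_force_formulas(self):
        w = init_weights(3)
        ens = EnsembleModel([FoldModel(w, 0.1, 1)], np.array([1.0]), TrainConfig())
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(8, 3))
        y = rng.normal(size=8)
        yhat = forward(w, X)
        m = evaluate(ens, X, y)
        assert m.rmse == pytest.approx(np.sqrt(np.mean((y - yhat) ** 2)))
        assert m.r2 == pytest.approx(
            1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2))


class TestSerialization:
    def test_round_trip_is_bit_exact(self):
        X, y = linear_rows(20, seed=7, noise=0.2)
        ens = train_ensemble(X, y, TrainConfig(max_epochs=100, patience=10,
                                               k=4, seed=3))
        payload = json.loads(json.dumps(ensemble_to_dict(ens)))
        back = ensemble_from_dict(payload)
        assert np.array_equal(back.ensemble_weights, ens.ensemble_weights)
        for fa, fb in zip(ens.folds, back.folds):
            assert fa.val_loss == fb.val_loss
            assert all(np.array_equal(pa, pb) for pa, pb
                       in zip(fa.weights.params(), fb.weights.params()))
        probe = np.array([[0.3, -0.2, 0.9]])
        assert predict(back, probe) == predict(ens, probe)
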