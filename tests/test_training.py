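"""End-to-end training behavior: determinism, gradients, recovery."""
import numpy as np
import pytest

import hnet
from hnet import TrainConfig, TrainingError
from hnet._nn import DenseMLP
from hnet.hypernet import TargetNetSpec, _HNetCore, _stabilize_hyper_output
from hnet.synthetic_data import generate_linear_dgp


def _tiny_linear(n=300, seed=0, noise=0.05):
    ds, oracle = generate_linear_dgp(n=n, p=2, slope_fn=2.0, intercept_fn=0.5,
                                     confounding_strength=0.0,
                                     noise_sd=noise, seed=seed)
    return ds, oracle


FAST = TrainConfig(max_epochs=120, n_restarts=1)


class TestSeededDeterminism:
    def test_same_seed_bit_identical_predictions(self, nie_instance):
        train, test, _ = nie_instance
        m1 = hnet.fit(train, FAST, seed=3)
        m2 = hnet.fit(train, FAST, seed=3)
        np.testing.assert_array_equal(m1.forward_batch(test.X, test.T),
                                      m2.forward_batch(test.X, test.T))

    def test_different_seed_differs(self, nie_instance):
        train, test, _ = nie_instance
        m1 = hnet.fit(train, FAST, seed=3)
        m3 = hnet.fit(train, FAST, seed=4)
        assert not np.array_equal(m1.forward_batch(test.X, test.T),
                                  m3.forward_batch(test.X, test.T))

    def test_slearner_same_seed_identical(self, nie_instance):
        train, test, _ = nie_instance
        s1 = hnet.fit_slearner(train, FAST, seed=5)
        s2 = hnet.fit_slearner(train, FAST, seed=5)
        np.testing.assert_array_equal(s1.forward_batch(test.X, test.T),
                                      s2.forward_batch(test.X, test.T))


class TestTrainingProgress:
    def test_loss_decreases_from_initialization(self, fitted_hnet):
        h = fitted_hnet.history
        assert h["final_train_loss"] < h["initial_train_loss"]

    def test_beats_mean_predictor_on_benchmark(self, nie_instance, fitted_hnet):
        train, _, _ = nie_instance
        mse = hnet.mse_loss(fitted_hnet, (train.X, train.T, train.Y))
        assert mse < train.Y.var()

    def test_divergence_raises_training_error(self, nie_instance):
        train, _, _ = nie_instance
        bad = TrainConfig(learning_rate=1e6, max_epochs=20, n_restarts=1,
                          ema_decay=None)
        with pytest.raises(TrainingError):
            hnet.fit(train, bad, seed=0)


class TestGradientCorrectness:
    def test_composite_gradient_matches_finite_differences(self):
        # tiny model: k=2, m<=10, n=4; verifies the gradient flows through
        # the generated weights end to end
        rng = np.random.default_rng(0)
        spec = TargetNetSpec(input_dim=1, hidden_widths=(2,))
        enc = DenseMLP([3, 4, 2], "elu", rng=rng)
        hyp = DenseMLP([2, 4, spec.param_count], "elu", rng=rng)
        _stabilize_hyper_output(hyp, spec, 0.1, rng)
        core = _HNetCore(enc, hyp, spec)
        X = rng.normal(size=(4, 3))
        T = rng.uniform(size=(4, 1))
        Y = rng.normal(size=4)

        def loss():
            return np.mean((core.forward(X, T) - Y) ** 2)

        cache = {}
        pred = core.forward(X, T, cache)
        grads = core.backward(cache, 2.0 / 4 * (pred - Y))
        eps = 1e-6
        for p, g in zip(core.params(), grads):
            flat_p, flat_g = p.ravel(), g.ravel()
            for j in range(flat_p.size):
                old = flat_p[j]
                flat_p[j] = old + eps
                lp = loss()
                flat_p[j] = old - eps
                lm = loss()
                flat_p[j] = old
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(flat_g[j]), 1e-8)
                assert abs(fd - flat_g[j]) / denom < 1e-3


class TestInstanceSpecificity:
    def test_distinct_rows_get_distinct_generated_weights(self, fitted_hnet,
                                                          nie_instance):
        _, test, _ = nie_instance
        omega = fitted_hnet.generate_weights(test.X[:10])
        # after training on a heterogeneous-effect DGP the generated weight
        # vectors must differ across units (non-degenerate hypernetwork)
        spread = np.ptp(omega, axis=0)
        assert spread.max() > 1e-6

    def test_identical_rows_get_identical_curves(self, fitted_hnet,
                                                 nie_instance, grid65):
        _, test, _ = nie_instance
        X = np.vstack([test.X[0], test.X[0]])
        curves = fitted_hnet.predict_curves(X, grid65)
        np.testing.assert_array_equal(curves[0], curves[1])


class TestParameterRecovery:
    def test_linear_slope_recovered(self, grid65):
        ds, _ = _tiny_linear(n=1500, seed=1)
        model = hnet.fit(ds, TrainConfig(max_epochs=250, n_restarts=1), seed=0)
        x_mid = np.full(2, 0.5)
        curve = model.predict_curve(x_mid, grid65)
        slope = np.polyfit(grid65.points, curve, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.10)


class TestPredictCurve:
    def test_curve_matches_per_point_forward(self, fitted_hnet, nie_instance,
                                             grid65):
        _, test, _ = nie_instance
        x = test.X[3]
        curve = fitted_hnet.predict_curve(x, grid65)
        pointwise = np.array([
            fitted_hnet.forward_batch(x[None, :], np.array([[t]]))[0]
            for t in grid65.points
        ])
        assert np.max(np.abs(curve - pointwise)) < 1e-6

    def test_extrapolation_warns(self, fitted_hnet):
        wide = hnet.DoseGrid.uniform(-1.0, 2.0, 5)
        with pytest.warns(hnet.ExtrapolationWarning):
            fitted_hnet.predict_curve(np.full(6, 0.5), wide)

    def test_contrast_identities(self, fitted_hnet):
        x = np.full(6, 0.3)
        assert fitted_hnet.contrast(x, 0.4, 0.4) == 0.0
        ab = fitted_hnet.contrast(x, 0.2, 0.8)
        ba = fitted_hnet.contrast(x, 0.8, 0.2)
        assert ab == pytest.approx(-ba)

    def test_slearner_curve_matches_per_point_forward(self, fitted_slearner,
                                                      nie_instance, grid65):
        _, test, _ = nie_instance
        x = test.X[5]
        curve = fitted_slearner.predict_curve(x, grid65)
        pointwise = np.array([
            fitted_slearner.forward_batch(x[None, :], np.array([[t]]))[0]
            for t in grid65.points
        ])
        assert np.max(np.abs(curve - pointwise)) < 1e-6


class TestCapacityParity:
    def test_ablation_parameter_counts_within_factor_two(self, fitted_hnet,
                                                         fitted_slearner):
        ratio = fitted_slearner.n_params / fitted_hnet.n_params
        assert 0.5 <= ratio <= 2.0


class TestModelSerialization:
    def test_save_load_round_trip(self, fitted_hnet, nie_instance, tmp_path):
        _, test, _ = nie_instance
        path = tmp_path / "model.npz"
        fitted_hnet.save(path)
        back = hnet.HNetModel.load(path)
        np.testing.assert_array_equal(back.forward_batch(test.X, test.T),
                                      fitted_hnet.forward_batch(test.X, test.T))
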