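"""Weight packing, target-network evaluation and the composite forward pass."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hnet
from hnet import ShapeError, TargetNetSpec, TrainConfig
from hnet.hypernet import (_target_backward, _target_curves, _target_forward,
                           apply_target_network, pack_weights,
                           target_param_count, unpack_weights)


def _enumerate_params(spec):
    """Oracle: instantiate the per-layer arrays and count scalars."""
    total = 0
    dims = spec.layer_dims
    for fi, fo in zip(dims[:-1], dims[1:]):
        total += np.zeros((fo, fi)).size + np.zeros(fo).size
    return total


class TestTargetParamCount:
    @pytest.mark.parametrize("tau,hidden,expected", [
        (1, (), 2),          # affine 1->1: one weight + one bias
        (1, (16,), 49),      # (1*16+16) + (16*1+1)
        (3, (8, 8), 113),    # (3*8+8)+(8*8+8)+(8*1+1)
    ])
    def test_hand_counts(self, tau, hidden, expected):
        spec = TargetNetSpec(input_dim=tau, hidden_widths=hidden)
        assert target_param_count(spec) == expected

    @given(tau=st.integers(1, 4),
           hidden=st.lists(st.integers(1, 12), max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_matches_enumeration_oracle(self, tau, hidden):
        spec = TargetNetSpec(input_dim=tau, hidden_widths=tuple(hidden))
        assert target_param_count(spec) == _enumerate_params(spec)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            TargetNetSpec(input_dim=0)
        with pytest.raises(ValueError):
            TargetNetSpec(hidden_widths=(0,))


class TestPackUnpack:
    def test_zero_vector(self):
        spec = TargetNetSpec(input_dim=1, hidden_widths=(2,))
        layers = unpack_weights(np.zeros(spec.param_count), spec)
        for w, b in layers:
            assert not w.any() and not b.any()

    def test_documented_layout(self):
        # spec 1->[2]->1: the first two entries are layer-1 weights (2x1
        # matrix, row-major), then the two layer-1 biases, then layer 2.
        spec = TargetNetSpec(input_dim=1, hidden_widths=(2,))
        omega = np.arange(1.0, spec.param_count + 1)
        (w1, b1), (w2, b2) = unpack_weights(omega, spec)
        np.testing.assert_array_equal(w1, [[1.0], [2.0]])
        np.testing.assert_array_equal(b1, [3.0, 4.0])
        np.testing.assert_array_equal(w2, [[5.0, 6.0]])
        np.testing.assert_array_equal(b2, [7.0])

    @given(tau=st.integers(1, 3),
           hidden=st.lists(st.integers(1, 8), max_size=3),
           seed=st.integers(0, 2**16))
    @settings(max_examples=60, deadline=None)
    def test_bijection_property(self, tau, hidden, seed):
        spec = TargetNetSpec(input_dim=tau, hidden_widths=tuple(hidden))
        omega = np.random.default_rng(seed).normal(size=spec.param_count)
        round_trip = pack_weights(unpack_weights(omega, spec), spec)
        np.testing.assert_array_equal(round_trip, omega)

    def test_wrong_length_reports_m(self):
        spec = TargetNetSpec(input_dim=1, hidden_widths=(16,))
        with pytest.raises(ShapeError, match="49"):
            unpack_weights(np.zeros(48), spec)


class TestApplyTargetNetwork:
    def test_zero_network_is_zero_everywhere(self):
        spec = TargetNetSpec(input_dim=1, hidden_widths=(4,))
        for t in (0.0, 0.3, -2.0):
            assert apply_target_network(np.zeros(spec.param_count), t, spec) == 0.0

    def test_affine_network_by_hand(self):
        # no hidden layer: output = w*t + b = 2*0.25 + 0.5 = 1.0
        spec = TargetNetSpec(input_dim=1, hidden_widths=())
        assert apply_target_network(np.array([2.0, 0.5]), 0.25, spec) == pytest.approx(1.0)

    def test_two_layer_manual_composition(self):
        # 1->[1]->1 with elu: t=0.5, u1 = 3*0.5 - 0.5 = 1.0 (positive, so
        # elu(u1)=u1), out = -2*1.0 + 0.25 = -1.75
        spec = TargetNetSpec(input_dim=1, hidden_widths=(1,), activation="elu")
        omega = np.array([3.0, -0.5, -2.0, 0.25])
        assert apply_target_network(omega, 0.5, spec) == pytest.approx(-1.75)

    def test_dimension_mismatch(self):
        spec = TargetNetSpec(input_dim=2, hidden_widths=())
        with pytest.raises(ShapeError):
            apply_target_network(np.zeros(3), 0.5, spec)


class TestBatchedTargetEvaluation:
    def test_batched_equals_per_sample_loop(self, rng):
        spec = TargetNetSpec(input_dim=2, hidden_widths=(8, 4))
        n = 64
        omega = rng.normal(size=(n, spec.param_count))
        T = rng.normal(size=(n, 2))
        batched = _target_forward(omega, T, spec)
        looped = np.array([apply_target_network(omega[i], T[i], spec)
                           for i in range(n)])
        np.testing.assert_allclose(batched, looped, atol=1e-10)

    def test_curves_match_pointwise_forward(self, rng):
        spec = TargetNetSpec(input_dim=1, hidden_widths=(8,))
        omega = rng.normal(size=(5, spec.param_count))
        ts = np.linspace(0, 1, 9)
        curves = _target_curves(omega, ts, spec)
        for j, t in enumerate(ts):
            col = _target_forward(omega, np.full((5, 1), t), spec)
            np.testing.assert_allclose(curves[:, j], col, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        spec = TargetNetSpec(input_dim=1, hidden_widths=(3,))
        n = 4
        omega = rng.normal(size=(n, spec.param_count))
        T = rng.uniform(size=(n, 1))
        cache = []
        _target_forward(omega, T, spec, cache)
        g = _target_backward(cache, np.ones(n), spec)
        eps = 1e-6
        for i in range(n):
            for j in range(spec.param_count):
                op, om = omega.copy(), omega.copy()
                op[i, j] += eps
                om[i, j] -= eps
                fd = (_target_forward(op, T, spec)[i]
                      - _target_forward(om, T, spec)[i]) / (2 * eps)
                assert g[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestForwardBatch:
    def test_batch_of_one_equals_scalar_pipeline(self, fitted_hnet, nie_instance):
        _, test, _ = nie_instance
        x, t = test.X[:1], test.T[:1]
        full = fitted_hnet.forward_batch(test.X[:8], test.T[:8])
        one = fitted_hnet.forward_batch(x, t)
        assert one[0] == pytest.approx(full[0], abs=1e-10)

    def test_batched_vs_looped(self, fitted_hnet, nie_instance):
        _, test, _ = nie_instance
        X, T = test.X[:64], test.T[:64]
        batched = fitted_hnet.forward_batch(X, T)
        looped = np.array([fitted_hnet.forward_batch(X[i:i+1], T[i:i+1])[0]
                           for i in range(64)])
        assert np.max(np.abs(batched - looped)) < 1e-5

    def test_row_permutation_equivariance(self, fitted_hnet, nie_instance):
        _, test, _ = nie_instance
        X, T = test.X[:16], test.T[:16]
        perm = np.random.default_rng(0).permutation(16)
        np.testing.assert_allclose(fitted_hnet.forward_batch(X, T)[perm],
                                   fitted_hnet.forward_batch(X[perm], T[perm]),
                                   atol=1e-12)

    def test_generated_weight_vector_has_length_m(self, fitted_hnet, nie_instance):
        _, test, _ = nie_instance
        omega = fitted_hnet.generate_weights(test.X[:3])
        assert omega.shape == (3, fitted_hnet.target_spec.param_count)


class TestMseLoss:
    def test_zero_when_predictions_equal_targets(self, fitted_hnet, nie_instance):
        _, test, _ = nie_instance
        pred = fitted_hnet.forward_batch(test.X, test.T)
        assert hnet.mse_loss(fitted_hnet, (test.X, test.T, pred)) == pytest.approx(0.0)

    def test_matches_direct_recomputation(self, fitted_hnet, nie_instance):
        _, test, _ = nie_instance
        batch = (test.X[:32], test.T[:32], test.Y[:32])
        direct = np.mean((test.Y[:32]
                          - fitted_hnet.forward_batch(*batch[:2])) ** 2)
        assert hnet.mse_loss(fitted_hnet, batch) == pytest.approx(direct)

    def test_empty_batch_rejected(self, fitted_hnet):
        with pytest.raises(ValueError):
            hnet.mse_loss(fitted_hnet, (np.empty((0, 6)), np.empty((0, 1)),
                                        np.empty(0)))
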