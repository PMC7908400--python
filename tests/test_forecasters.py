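import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decompcast.series import SlidingWindowDataset, TimeSeries
from decompcast.forecasters import (
    ANFISModel,
    BPNNConfig,
    GMDHConfig,
    TrainedBPNN,
    anfis_fcm_build,
    anfis_forward,
    anfis_init_grid,
    anfis_predict,
    anfis_train,
    bpnn_predict,
    bpnn_train,
    fcm_cluster,
    gmdh_fit,
    gmdh_predict,
    rolling_forecast,
)


class TestBPNN:
    def test_reaches_goal_on_linear_target(self, linear_dataset):
        model = bpnn_train(linear_dataset, BPNNConfig(seed=1))
        assert model.error_trace[-1] < 0.00004
        assert len(model.error_trace) <= 1000

    def test_zero_epochs_returns_seeded_init(self, linear_dataset):
        a = bpnn_train(linear_dataset, BPNNConfig(seed=7, max_epochs=0))
        b = bpnn_train(linear_dataset, BPNNConfig(seed=7, max_epochs=0))
        np.testing.assert_array_equal(a.w_hidden, b.w_hidden)
        assert len(a.error_trace) == 0

    def test_seeded_determinism(self, linear_dataset):
        a = bpnn_train(linear_dataset, BPNNConfig(seed=3, max_epochs=20))
        b = bpnn_train(linear_dataset, BPNNConfig(seed=3, max_epochs=20))
        np.testing.assert_array_equal(a.w_hidden, b.w_hidden)
        np.testing.assert_array_equal(a.w_output, b.w_output)

    def test_zero_weights_predict_zero(self):
        model = TrainedBPNN(
            w_hidden=np.zeros((4, 9)),
            b_hidden=np.zeros(9),
            w_output=np.zeros((9, 1)),
            b_output=np.zeros(1),
            error_trace=np.empty(0),
            config=BPNNConfig(),
        )
        np.testing.assert_array_equal(bpnn_predict(model, np.random.rand(5, 4)), np.zeros(5))

    def test_predict_contract(self, linear_dataset):
        model = bpnn_train(linear_dataset, BPNNConfig(seed=0, max_epochs=5))
        assert len(bpnn_predict(model, np.empty((0, 4)))) == 0
        x = np.random.rand(3, 4)
        np.testing.assert_array_equal(bpnn_predict(model, x), bpnn_predict(model, x))
        with pytest.raises(ValueError, match="width"):
            bpnn_predict(model, np.random.rand(3, 5))

    def test_empty_dataset_rejected(self):
        empty = SlidingWindowDataset(inputs=np.empty((0, 4)), targets=np.empty(0), lag=4)
        with pytest.raises(ValueError, match="empty"):
            bpnn_train(empty, BPNNConfig())


class TestANFISStructure:
    def test_grid_rule_counts(self):
        assert anfis_init_grid(n_input=4, mfs_per_input=2).n_rules == 16
        assert anfis_init_grid(n_input=4, mfs_per_input=1).n_rules == 1

    def test_grid_centers_evenly_spaced(self):
        model = anfis_init_grid(n_input=1, mfs_per_input=2, input_range=(0.0, 1.0))
        assert sorted(model.centers.ravel().tolist()) == [0.0, 1.0]

    def test_single_rule_forward_is_consequent(self):
        model = ANFISModel(
            centers=np.array([[0.5, 0.5]]),
            spreads=np.full((1, 2), 0.5),
            consequents=np.array([[2.0, -1.0, 0.25]]),
        )
        x = np.array([0.3, 0.8])
        out, w, w_bar = anfis_forward(model, x)
        assert w_bar[0] == pytest.approx(1.0)
        assert out == pytest.approx(2.0 * 0.3 - 1.0 * 0.8 + 0.25)

    @given(st.lists(st.floats(-0.5, 1.5), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_normalized_firings_sum_to_one(self, x):
        model = anfis_init_grid(n_input=4, mfs_per_input=2)
        _, _, w_bar = anfis_forward(model, np.array(x))
        assert w_bar.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_rules_cancel_at_midpoint(self):
        # two rules symmetric about x=0.5 with constant consequents +1 / -1
        model = ANFISModel(
            centers=np.array([[0.0], [1.0]]),
            spreads=np.full((2, 1), 0.4),
            consequents=np.array([[0.0, 1.0], [0.0, -1.0]]),
        )
        out, _, w_bar = anfis_forward(model, np.array([0.5]))
        assert w_bar[0] == pytest.approx(w_bar[1])
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_input_outside_support_rejected(self):
        model = ANFISModel(
            centers=np.array([[0.0, 0.0, 0.0, 0.0]]),
            spreads=np.full((1, 4), 1e-3),
            consequents=np.zeros((1, 5)),
        )
        with pytest.raises(ValueError, match="fuzzy support"):
            anfis_forward(model, np.full(4, 100.0))


class TestANFISTraining:
    def test_lse_recovers_self_generated_data(self, linear_dataset):
        # premises frozen: data generated from the model's own consequents
        truth = anfis_init_grid(n_input=4, mfs_per_input=2)
        rng = np.random.default_rng(5)
        truth_consequents = rng.normal(size=truth.consequents.shape)
        truth = ANFISModel(
            centers=truth.centers, spreads=truth.spreads, consequents=truth_consequents
        )
        X = linear_dataset.inputs
        y = anfis_predict(truth, X)
        data = SlidingWindowDataset(inputs=X, targets=y, lag=4)
        fitted = anfis_train(truth, data, epochs=1, lr=0.0)
        mse = float(np.mean((anfis_predict(fitted, X) - y) ** 2))
        assert mse < 1e-10

    def test_zero_epochs_is_noop(self, linear_dataset):
        model = anfis_init_grid()
        same = anfis_train(model, linear_dataset, epochs=0)
        np.testing.assert_array_equal(same.consequents, model.consequents)
        np.testing.assert_array_equal(same.centers, model.centers)

    def test_lse_step_never_increases_mse(self, linear_dataset):
        # consecutive LSE-only refits (lr=0) keep the least-squares optimum
        model = anfis_train(anfis_init_grid(), linear_dataset, epochs=1, lr=0.0)
        mse1 = float(np.mean((anfis_predict(model, linear_dataset.inputs) - linear_dataset.targets) ** 2))
        model2 = anfis_train(model, linear_dataset, epochs=1, lr=0.0)
        mse2 = float(np.mean((anfis_predict(model2, linear_dataset.inputs) - linear_dataset.targets) ** 2))
        assert mse2 <= mse1 + 1e-12


class TestFCM:
    def test_well_separated_blobs(self):
        points = np.array([-0.1, 0.0, 0.1, 9.9, 10.0, 10.1])
        result = fcm_cluster(points, c=2, m=2.0, seed=0)
        centers = np.sort(result.centers.ravel())
        # oracle: the blob means 0 and 10 (k-means solution for this data)
        assert abs(centers[0] - 0.0) < 0.05
        assert abs(centers[1] - 10.0) < 0.05

    @given(st.integers(0, 40))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_membership_columns_sum_to_one_and_cost_monotone(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(30, 2))
        result = fcm_cluster(points, c=3, m=2.0, seed=seed)
        np.testing.assert_allclose(result.membership.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(np.diff(result.cost_trace) <= 1e-12)

    def test_coincident_point_gets_crisp_membership(self):
        points = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        result = fcm_cluster(points, c=2, m=2.0, seed=1)
        # centers converge onto the duplicated values -> crisp columns
        assert np.all(np.max(result.membership, axis=0) > 0.99)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError, match="c <= n"):
            fcm_cluster(np.arange(3.0), c=4)


class TestANFISFCM:
    def test_single_cluster_equals_linear_regression(self, linear_dataset):
        # one rule => normalized firing 1 => plain least-squares linear model
        model = anfis_fcm_build(linear_dataset, c=1, epochs=1, lr=0.0)
        X, y = linear_dataset.inputs, linear_dataset.targets
        Xa = np.hstack([X, np.ones((len(X), 1))])
        beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
        ols_mse = float(np.mean((Xa @ beta - y) ** 2))
        model_mse = float(np.mean((anfis_predict(model, X) - y) ** 2))
        assert model_mse == pytest.approx(ols_mse, abs=1e-10)

    def test_one_rule_per_cluster(self, linear_dataset):
        model = anfis_fcm_build(linear_dataset, c=9, epochs=1)
        assert model.n_rules == 9

    def test_seeded_determinism(self, linear_dataset):
        a = anfis_fcm_build(linear_dataset, c=5, seed=4, epochs=2)
        b = anfis_fcm_build(linear_dataset, c=5, seed=4, epochs=2)
        np.testing.assert_array_equal(a.centers, b.centers)
        np.testing.assert_array_equal(a.consequents, b.consequents)


class TestGMDH:
    def test_linear_target_recovered_exactly(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(60, 4))
        y = 1.0 + 2.0 * X[:, 0] + 3.0 * X[:, 1]
        data = SlidingWindowDataset(inputs=X, targets=y, lag=4)
        model = gmdh_fit(data)
        assert model.criterion < 1e-8

    def test_candidate_pool_is_all_pairs(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(40, 4))
        y = X[:, 0] * X[:, 1] + 0.1 * rng.normal(size=40)
        data = SlidingWindowDataset(inputs=X, targets=y, lag=4)
        model = gmdh_fit(data, GMDHConfig(max_layers=1, max_neurons=6))
        assert len(model.layers[0]) == 6  # C(4,2) candidates all survive

    def test_constant_target_fit(self):
        X = np.random.default_rng(4).uniform(0, 1, size=(30, 4))
        y = np.full(30, 3.25)
        data = SlidingWindowDataset(inputs=X, targets=y, lag=4)
        model = gmdh_fit(data)
        assert model.criterion == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(gmdh_predict(model, X), 3.25, atol=1e-9)

    def test_no_deterioration_rule(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(120, 4))
        y = np.sin(3 * X[:, 0]) + X[:, 1] * X[:, 2] + 0.05 * rng.normal(size=120)
        model = gmdh_fit(SlidingWindowDataset(inputs=X, targets=y, lag=4))
        bests = [min(n.score for n in layer) for layer in model.layers]
        assert model.criterion <= min(bests) + 1e-12
        assert all(b2 < b1 for b1, b2 in zip(bests, bests[1:]))

    def test_predict_contract(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, size=(30, 4))
        y = X[:, 0] + X[:, 3]
        model = gmdh_fit(SlidingWindowDataset(inputs=X, targets=y, lag=4))
        assert len(gmdh_predict(model, np.empty((0, 4)))) == 0
        with pytest.raises(ValueError, match="width"):
            gmdh_predict(model, np.random.rand(3, 5))


class _WindowMean:
    def predict(self, inputs):
        return np.mean(inputs, axis=1)


class TestRollingForecast:
    def test_hand_computed_example(self):
        preds = rolling_forecast(
            _WindowMean(),
            TimeSeries(values=np.array([1.0, 2.0, 3.0, 4.0])),
            TimeSeries(values=np.array([5.0, 6.0])),
            lag=4,
        )
        np.testing.assert_allclose(preds, [2.5, 3.5])

    def test_empty_horizon(self):
        out = rolling_forecast(_WindowMean(), np.arange(4.0), np.empty(0), lag=4)
        assert len(out) == 0

    def test_matches_explicit_loop(self):
        # oracle: one-at-a-time prediction with observed values rolling in
        rng = np.random.default_rng(8)
        hist = rng.normal(size=10)
        hor = rng.normal(size=7)
        lag = 4
        model = _WindowMean()
        expected = []
        window = list(hist[-lag:])
        for actual in hor:
            expected.append(float(np.mean(window)))
            window = window[1:] + [actual]
        np.testing.assert_allclose(rolling_forecast(model, hist, hor, lag), expected)

    def test_short_history_rejected(self):
        with pytest.raises(ValueError, match="shorter than lag"):
            rolling_forecast(_WindowMean(), np.arange(3.0), np.arange(2.0), lag=4)
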