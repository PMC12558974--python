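import numpy as np
import pytest

from hairsentinel.errors import ContractError, DomainError
from hairsentinel.forecasting.autograd import Adam, Tensor, concatenate, elu, sigmoid, softmax, stack, tanh
from hairsentinel.forecasting.tft import (GRNParams, SeriesWindow, TFTForecaster, glu, grn,
                                          make_windows, persistence_baseline, temporal_attention)


class TestAutograd:
    def _gradcheck(self, fn, x0, eps=1e-6, atol=1e-5):
        x = Tensor(x0.copy(), requires_grad=True)
        out = fn(x)
        out.sum().backward()
        analytic = x.grad.copy()
        numeric = np.zeros_like(x0)
        flat = x0.reshape(-1)
        num_flat = numeric.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(Tensor(x0)).data.sum()
            flat[i] = orig - eps
            lo = fn(Tensor(x0)).data.sum()
            flat[i] = orig
            num_flat[i] = (hi - lo) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, atol=atol)

    def test_elementwise_chain(self, rng):
        x0 = rng.normal(0, 1, (4, 3))
        self._gradcheck(lambda x: (sigmoid(x) * tanh(x) + elu(x * 2.0)) ** 2.0, x0)

    def test_matmul_softmax(self, rng):
        W = Tensor(rng.normal(0, 1, (3, 5)))
        M = Tensor(rng.normal(0, 1, (4, 5)))
        x0 = rng.normal(0, 1, (4, 3))
        self._gradcheck(lambda x: softmax(x @ W, axis=-1) * M, x0)

    def test_reductions_slicing_concat(self, rng):
        x0 = rng.normal(0, 1, (6, 4))

        def fn(x):
            a = x[:, :2].mean(axis=1, keepdims=True)
            b = x[:, 2:].sum(axis=1, keepdims=True)
            return concatenate([a, b], axis=1) * 3.0

        self._gradcheck(fn, x0)

    def test_stack_reshape(self, rng):
        x0 = rng.normal(0, 1, (3, 4))

        def fn(x):
            s = stack([x * 2.0, x ** 2.0], axis=1)  # (3, 2, 4)
            return s.reshape(3, 8)

        self._gradcheck(fn, x0)

    def test_adam_reduces_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 0.05


class TestGLU:
    def test_zero_gate_halves(self):
        np.testing.assert_allclose(glu([2.0, -4.0], [0.0, 0.0]), [1.0, -2.0])

    def test_saturation(self):
        np.testing.assert_allclose(glu([3.0], [50.0]), [3.0], atol=1e-12)

    def test_hand_values(self):
        # sigma(ln 3) = 3/4
        np.testing.assert_allclose(glu([2.0, -4.0], [np.log(3.0), 0.0]), [1.5, -2.0], atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            glu([1.0, 2.0], [1.0])


class TestGRN:
    def test_zero_weights_is_layernorm(self, rng):
        x = rng.normal(2, 3, 5)
        params = GRNParams.zeros(5, 8)
        out = grn(x, params)
        expected = (x - x.mean()) / np.sqrt(x.var() + 1e-10)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_output_moments(self, rng):
        params = GRNParams.init(6, 10, rng)
        out = grn(rng.normal(0, 1, (20, 6)), params)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.var(axis=1), 1.0, atol=1e-6)

    def test_matches_step_by_step_oracle(self, rng):
        """Scalar-by-scalar recomputation of the GRN on a fixed 3-vector."""
        params = GRNParams.init(3, 4, rng)
        x = np.array([0.5, -1.0, 2.0])
        # independent straight-line computation
        pre = params.W1.T @ x + params.b1
        hidden = np.array([v if v > 0 else np.exp(v) - 1 for v in pre])
        a = params.W2.T @ hidden + params.b2
        g = params.Wg.T @ hidden + params.bg
        gated = np.array([ai / (1 + np.exp(-gi)) for ai, gi in zip(a, g)])
        resid = x + gated
        expected = (resid - resid.mean()) / np.sqrt(resid.var() + 1e-10)
        np.testing.assert_allclose(grn(x, params), expected, atol=1e-9)

    def test_width_mismatch(self, rng):
        with pytest.raises(ContractError):
            grn(np.zeros(4), GRNParams.zeros(3, 5))


class TestTemporalAttention:
    def test_single_key(self):
        ctx, w = temporal_attention(np.ones((1, 2)), np.ones((1, 2)), [[7.0, 3.0]])
        np.testing.assert_allclose(w, [[1.0]])
        np.testing.assert_allclose(ctx, [[7.0, 3.0]])

    def test_identical_keys_uniform(self, rng):
        K = np.tile(rng.normal(0, 1, 3), (5, 1))
        V = rng.normal(0, 1, (5, 3))
        _, w = temporal_attention(rng.normal(0, 1, (2, 3)), K, V)
        np.testing.assert_allclose(w, np.full((2, 5), 0.2), atol=1e-12)

    def test_hand_softmax_two_keys(self):
        q = np.array([[1.0, 0.0]])
        K = np.array([[1.0, 0.0], [0.0, 1.0]])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        d_k = 2
        ctx, w = temporal_attention(q, K, V, d_k)
        logits = np.array([1.0, 0.0]) / np.sqrt(2)
        expected = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(w[0], expected, atol=1e-9)
        np.testing.assert_allclose(ctx[0], expected @ V, atol=1e-9)

    def test_empty_keys(self):
        with pytest.raises(ContractError):
            temporal_attention(np.ones((1, 2)), np.empty((0, 2)), np.empty((0, 2)))


class TestWindows:
    def test_invariants(self, rng):
        with pytest.raises(DomainError):
            SeriesWindow(np.zeros((0, 1)), np.zeros(1), np.zeros(0), horizon=5)
        with pytest.raises(ContractError):
            SeriesWindow(np.zeros((5, 1)), np.zeros(1), np.full(5, np.nan), horizon=2)

    def test_no_leakage_split(self, rng):
        y = rng.normal(0, 1, 100)
        train, test = make_windows(y, np.zeros((100, 1)), window=10, horizon=5,
                                   train_fraction=0.7)
        split = 70
        # every training window's forecast span ends at or before the split
        for i, w in enumerate(train):
            assert i + 10 + 5 <= split
        # test windows forecast strictly beyond the split
        assert len(test) > 0
        assert len(train) + len(test) == 100 - 10 - 5 + 1

    def test_persistence(self):
        w = SeriesWindow(np.zeros((4, 1)), np.zeros(1),
                         np.array([1.0, 2.0, 0.5, 3.2]), horizon=3)
        np.testing.assert_allclose(persistence_baseline(w), [3.2, 3.2, 3.2])

    def test_persistence_random_walk_mse_law(self, rng):
        """Persistence MSE on a random walk grows like the increment variance
        times the horizon step, averaged over the horizon."""
        sigma = 0.5
        horizon = 6
        errs = []
        for _ in range(300):
            steps = rng.normal(0, sigma, 30 + horizon)
            y = np.cumsum(steps)
            w = SeriesWindow(np.zeros((30, 1)), np.zeros(1), y[:30], horizon=horizon,
                             future_targets=y[30:])
            errs.append(np.mean((persistence_baseline(w) - w.future_targets) ** 2))
        expected = sigma ** 2 * np.mean(np.arange(1, horizon + 1))
        assert np.mean(errs) == pytest.approx(expected, rel=0.15)


class TestTFTForecaster:
    def test_constant_series(self):
        y = np.full(60, 2.5)
        train, test = make_windows(y, np.zeros((60, 1)), window=10, horizon=4)
        model = TFTForecaster(hidden_size=8, epochs=30, learning_rate=3e-3,
                              dropout=0.0, seed=0).fit(train)
        res = model.predict(test[0])
        np.testing.assert_allclose(res.predictions, 2.5, atol=0.05)

    def test_noiseless_trend_beats_persistence(self):
        t = np.arange(150)
        y = 0.05 * t
        train, test = make_windows(y, np.zeros((150, 1)), window=20, horizon=5)
        model = TFTForecaster(hidden_size=16, epochs=150, learning_rate=3e-3,
                              dropout=0.0, seed=0).fit(train)
        p_mse = np.mean([np.mean((persistence_baseline(w) - w.future_targets) ** 2)
                         for w in test])
        assert model.score_mse(test) <= 0.1 * p_mse

    def test_loss_curve_decreases_on_trend(self):
        t = np.arange(100)
        train, _ = make_windows(0.05 * t, np.zeros((100, 1)), window=20, horizon=5,
                                train_fraction=1.0)
        model = TFTForecaster(hidden_size=8, epochs=60, learning_rate=3e-3,
                              dropout=0.0, seed=0).fit(train)
        curve = model.loss_curve_
        assert curve[-1] < curve[0]
        # allow optimizer jitter: smoothed curve must be non-increasing
        smooth = np.convolve(curve, np.ones(10) / 10, mode="valid")
        assert all(b <= a + 0.05 * abs(a) + 1e-6 for a, b in zip(smooth, smooth[5:]))

    def test_inference_deterministic_and_normalized(self, seasonal_series):
        y, cov = seasonal_series
        train, test = make_windows(y, cov, window=30, horizon=14)
        model = TFTForecaster(hidden_size=8, epochs=5, learning_rate=3e-3,
                              dropout=0.1, seed=0).fit(train)
        r1 = model.predict(test[0])
        r2 = model.predict(test[0])
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        # attention rows and variable-selection weights are distributions
        np.testing.assert_allclose(r1.attention_weights.sum(axis=1), 1.0, atol=1e-6)
        assert (r1.attention_weights >= 0).all()
        np.testing.assert_allclose(r1.variable_selection_weights.sum(), 1.0, atol=1e-6)
        assert (r1.variable_selection_weights >= 0).all()

    def test_seed_determinism_of_training(self):
        y = np.sin(np.arange(80) / 5.0)
        train, _ = make_windows(y, np.zeros((80, 1)), window=10, horizon=3,
                                train_fraction=1.0)
        m1 = TFTForecaster(hidden_size=8, epochs=10, dropout=0.1, seed=4).fit(train)
        m2 = TFTForecaster(hidden_size=8, epochs=10, dropout=0.1, seed=4).fit(train)
        assert m1.loss_curve_ == m2.loss_curve_

    def test_white_noise_no_pathology(self):
        """On white noise the trained model must not lose to persistence by
        more than 10%."""
        gen = np.random.default_rng(1)
        y = gen.normal(0, 1, 150)
        train, test = make_windows(y, np.zeros((150, 1)), window=20, horizon=7)
        model = TFTForecaster(hidden_size=8, epochs=60, learning_rate=3e-3,
                              dropout=0.0, seed=0).fit(train)
        p_mse = np.mean([np.mean((persistence_baseline(w) - w.future_targets) ** 2)
                         for w in test])
        assert model.score_mse(test) <= 1.1 * p_mse

    def test_unfitted_predict_rejected(self):
        w = SeriesWindow(np.zeros((5, 1)), np.zeros(1), np.arange(5.0), horizon=2)
        with pytest.raises(ContractError):
            TFTForecaster().predict(w)

    def test_multihead_flag(self):
        y = np.sin(np.arange(60) / 4.0)
        train, test = make_windows(y, np.zeros((60, 1)), window=10, horizon=3)
        model = TFTForecaster(hidden_size=8, heads=2, epochs=5, dropout=0.0, seed=0).fit(train)
        res = model.predict(test[0])
        np.testing.assert_allclose(res.attention_weights.sum(axis=1), 1.0, atol=1e-6)
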