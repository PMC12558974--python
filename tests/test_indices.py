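import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairsentinel.errors import ContractError, DomainError, FittingError, LookupError_, RefinementError
from hairsentinel.indices import (EMRefiner, LinearModel, RDATable, em_refine, fit_linear_model,
                                  hormonal_fluctuation_index, nutrient_deficiency_score,
                                  nutrient_intake_ratio, scalp_health_score, stress_impact_score)


class TestStressImpactScore:
    @pytest.mark.parametrize("stress,freq,expected", [
        (7, 7, 7.0),
        (5, 0, 0.0),
        (5, 3, 15.0 / 7.0),
    ])
    def test_values(self, stress, freq, expected):
        assert stress_impact_score(stress, freq) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        with pytest.raises(DomainError):
            stress_impact_score(11, 3)
        with pytest.raises(DomainError):
            stress_impact_score(5, 8)


class TestNutrientRatio:
    def test_full_adherence(self, rda):
        assert nutrient_intake_ratio(7, "protein", "male", 30, rda) == pytest.approx(1.0)

    def test_zero(self, rda):
        assert nutrient_intake_ratio(0, "iron", "female", 25, rda) == 0.0

    def test_hand_arithmetic(self):
        rda = RDATable()
        rda.add("protein", "male", 0, 100, per_day=50, per_week=350)
        assert nutrient_intake_ratio(3, "protein", "male", 30, rda) == pytest.approx(3 * 50 / 350)

    def test_missing_entry(self, rda):
        with pytest.raises(LookupError_):
            nutrient_intake_ratio(3, "zinc", "male", 30, rda)


class TestDeficiencyScore:
    @pytest.mark.parametrize("p,o,i,expected", [
        (0, 0, 0, 1.0),
        (1, 1, 1, -2.0),
        (0.4286, 0.2, 0.1, 0.2714),
    ])
    def test_values(self, p, o, i, expected):
        assert nutrient_deficiency_score(p, o, i) == pytest.approx(expected, abs=1e-9)

    def test_negative_ratio_rejected(self):
        with pytest.raises(DomainError):
            nutrient_deficiency_score(-0.1, 0, 0)

    def test_sum_identity(self, rng):
        ratios = rng.random((100, 3))
        nds = nutrient_deficiency_score(ratios[:, 0], ratios[:, 1], ratios[:, 2])
        np.testing.assert_allclose(nds + ratios.sum(axis=1), 1.0, atol=1e-12)


class TestHFI:
    @pytest.mark.parametrize("args,expected", [
        ((0, 0, 0, 0, 0, 0, 0), 0.0),
        ((2, 5, 3, 10, 0, 0, 0), 0.0),       # numerator cancels
        ((3, 7, 4, 6, 0.5, 0.3, 0.2), 4.0),  # 8 / 2
    ])
    def test_values(self, args, expected):
        assert hormonal_fluctuation_index(*args) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(sis=st.floats(0, 10), stress=st.floats(0, 10), rate=st.floats(1, 5),
           sleep=st.floats(0, 14), p=st.floats(0, 1.5), i=st.floats(0, 1.5),
           o=st.floats(0, 1.5), bump=st.floats(0.01, 2))
    def test_monotonicity(self, sis, stress, rate, sleep, p, i, o, bump):
        base = hormonal_fluctuation_index(sis, stress, rate, sleep, p, i, o)
        assert hormonal_fluctuation_index(sis + bump, stress, rate, sleep, p, i, o) >= base
        assert hormonal_fluctuation_index(sis, stress + bump, rate, sleep, p, i, o) >= base
        assert hormonal_fluctuation_index(sis, stress, rate + bump, sleep, p, i, o) >= base
        assert hormonal_fluctuation_index(sis, stress, rate, sleep + bump, p, i, o) <= base
        if base > 0:  # ratios shrink HFI only when the numerator is positive
            assert hormonal_fluctuation_index(sis, stress, rate, sleep, p + bump, i, o) <= base

    def test_always_finite(self, rng):
        vals = hormonal_fluctuation_index(
            rng.random(1000) * 10, rng.random(1000) * 10, rng.integers(1, 6, 1000),
            rng.random(1000) * 12, rng.random(1000), rng.random(1000), rng.random(1000))
        assert np.isfinite(vals).all()


class TestLinearModel:
    def test_constant_target(self, rng):
        X = rng.random((50, 3))
        model = fit_linear_model(X, np.full(50, 3.0))
        assert model.intercept == pytest.approx(3.0, abs=1e-9)
        for w in model.coefficients.values():
            assert w == pytest.approx(0.0, abs=1e-9)

    def test_exact_fit(self, rng):
        x = rng.random(40)
        model = fit_linear_model(x[:, None], 2 * x, ["x"])
        assert model.coefficients["x"] == pytest.approx(2.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-9)

    def test_parameter_recovery(self, rng):
        w_true = np.array([1.5, -0.5, 0.8])
        X = rng.normal(0, 1, (5000, 3))
        y = X @ w_true + rng.normal(0, 0.1, 5000)
        model = fit_linear_model(X, y, ["a", "b", "c"])
        recovered = np.array([model.coefficients[k] for k in ("a", "b", "c")])
        np.testing.assert_allclose(recovered, w_true, atol=0.05)

    def test_matches_pinv_oracle(self, rng):
        """OLS equals the normal-equations/pseudo-inverse solution on 50
        random small designs."""
        for _ in range(50):
            n, d = rng.integers(8, 20), rng.integers(1, 4)
            X = rng.normal(0, 1, (n, d))
            y = rng.normal(0, 1, n)
            model = fit_linear_model(X, y)
            design = np.column_stack([np.ones(n), X])
            beta = np.linalg.pinv(design) @ y
            got = np.array([model.intercept] + [model.coefficients[f"x{j}"] for j in range(d)])
            np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(0, 1, (100, 2))
        y = X @ [1.0, -2.0] + rng.normal(0, 0.5, 100)
        model = fit_linear_model(X, y, ["a", "b"])
        sm_fit = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            [model.intercept, model.coefficients["a"], model.coefficients["b"]],
            sm_fit.params, atol=1e-10)

    def test_rank_deficient_names_columns(self, rng):
        x = rng.normal(0, 1, 30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(FittingError, match="collinear"):
            fit_linear_model(X, rng.normal(0, 1, 30), ["a", "a_doubled"])

    def test_training_mse_beats_zero_model(self, rng):
        X = rng.normal(0, 1, (60, 2))
        y = X @ [0.5, 0.5] + rng.normal(0, 1, 60)
        model = fit_linear_model(X, y, ["a", "b"])
        pred = model.predict_matrix(X, ["a", "b"])
        assert np.mean((y - pred) ** 2) <= np.mean(y ** 2)


class TestScalpHealthScore:
    def test_intercept_only(self):
        m = LinearModel(1.0, {"shampoo_type": 0, "conditioner_used": 0, "hair_strength": 0}, 0.0)
        assert scalp_health_score({"shampoo_type": 2, "conditioner_used": 1,
                                   "hair_strength": 7}, m) == 1.0

    def test_hand_arithmetic(self):
        m = LinearModel(0.0, {"shampoo_type": 1, "conditioner_used": 1, "hair_strength": 1}, 0.0)
        assert scalp_health_score({"shampoo_type": 1, "conditioner_used": 0,
                                   "hair_strength": 5}, m) == 6.0

    def test_linearity(self, rng):
        m = LinearModel(0.3, {"shampoo_type": 0.5, "conditioner_used": -1.2,
                              "hair_strength": 0.1}, 0.0)
        feats = rng.random((20, 3))
        names = ["shampoo_type", "conditioner_used", "hair_strength"]
        scores = [scalp_health_score(dict(zip(names, f)), m) for f in feats]
        mean_score = scalp_health_score(dict(zip(names, feats.mean(axis=0))), m)
        assert mean_score == pytest.approx(np.mean(scores), abs=1e-10)

    def test_name_mismatch(self):
        m = LinearModel(0.0, {"shampoo_type": 1.0}, 0.0)
        with pytest.raises(ContractError):
            scalp_health_score({"wrong_name": 1.0}, m)


def _naive_em(y, rho, iters=10_000):
    """Straight-line EM loop: the independent fixed-point oracle."""
    y = np.asarray(y, dtype=float)
    mask = ~np.isnan(y)
    mu = y[mask].mean()
    for _ in range(iters):
        z = np.where(mask, mu + rho * (y - mu), mu)
        mu = z.mean()
    z = np.where(mask, mu + rho * (y - mu), mu)
    return mu, z.var(), z


class TestEMRefine:
    def test_identity_weighting(self, rng):
        y = rng.normal(5, 2, 40)
        state = em_refine(y, rho=1.0)
        np.testing.assert_allclose(state.refined, y, atol=1e-12)
        assert state.mu == pytest.approx(y.mean(), abs=1e-9)
        assert state.sigma2 == pytest.approx(y.var(), abs=1e-9)

    def test_full_shrinkage(self, rng):
        y = rng.normal(0, 1, 30)
        state = em_refine(y, rho=0.0)
        np.testing.assert_allclose(state.refined, y.mean(), atol=1e-9)
        assert state.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_fixed_point_matches_naive_loop(self):
        y = np.array([1.0, 3.0, np.nan])
        state = em_refine(y, rho=0.5, tol=1e-14, max_iter=10_000)
        mu, var, z = _naive_em(y, 0.5)
        assert state.mu == pytest.approx(mu, abs=1e-8)
        assert state.sigma2 == pytest.approx(var, abs=1e-8)
        np.testing.assert_allclose(state.refined, z, atol=1e-8)
        assert state.converged

    def test_fixed_point_with_30pct_missing(self, rng):
        y = rng.normal(2, 1, 100)
        y[rng.choice(100, 30, replace=False)] = np.nan
        state = em_refine(y, rho=0.5, tol=1e-14, max_iter=10_000)
        mu, var, z = _naive_em(y, 0.5)
        assert state.mu == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(state.refined, z, atol=1e-8)

    def test_too_few_observed(self):
        with pytest.raises(RefinementError):
            em_refine([1.0, np.nan, np.nan], rho=0.5)
        with pytest.raises(DomainError):
            em_refine([1.0, 2.0], rho=1.5)

    def test_estimator_wrapper(self, rng):
        y = rng.normal(0, 1, 25)
        ref = EMRefiner(rho=0.7).fit(y)
        state = em_refine(y, rho=0.7)
        assert ref.mu_ == state.mu
        np.testing.assert_array_equal(ref.refined_, state.refined)
        assert EMRefiner().set_params(rho=0.2).get_params()["rho"] == 0.2
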