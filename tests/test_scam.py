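"""Shape-constrained additive model engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from invadibe.scam import (ScamRegressor, TermSpec, _beta_from_gamma,
                           _design, build_monotone_basis, drop_null_smooths,
                           fit_scam)


def quasi_data(rng, n=400, trials=200, slope=0.3, intercept=-2.0):
    x = rng.uniform(0, 10, n)
    mu = expit(intercept + slope * x)
    y = rng.binomial(trials, mu) / trials
    return pd.DataFrame({"x": x}), y, mu


class TestMonotoneBasis:
    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_monotone_basis(np.ones(20), 6)

    def test_few_distinct_values_reduce_k(self):
        with pytest.warns(UserWarning, match="reducing"):
            B, knots, k = build_monotone_basis(np.repeat([0., 1, 2, 3, 4], 4),
                                               10)
        assert B.shape[1] == k <= 10

    def test_any_gamma_yields_nondecreasing_curve(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(0, 1, 50))
        B, knots, k = build_monotone_basis(x, 8)
        for _ in range(10):
            beta = _beta_from_gamma(rng.normal(0, 2, k - 1))
            f = _design(np.linspace(0, 1, 200), knots) @ beta
            assert np.all(np.diff(f) >= -1e-10)

    def test_linear_functions_representable_with_positive_increments(self):
        # beta at the Greville abscissae reproduces f(x) = x exactly, and
        # those abscissae are strictly increasing, i.e. reachable through
        # the cumulative-sum-of-exponentials map
        x = np.linspace(0, 1, 40)
        B, knots, k = build_monotone_basis(x, 8)
        greville = np.array([knots[j + 1: j + 4].mean() for j in range(k)])
        assert np.all(np.diff(greville) > 0)
        grid = np.linspace(0, 1, 100)
        f = _design(grid, knots) @ greville
        assert np.max(np.abs(f - grid)) < 1e-12

    def test_recovers_monotone_cubic_by_penalized_least_squares(self):
        # direct least-squares oracle in the transformed space
        from scipy.optimize import minimize
        x = np.arange(1, 21, dtype=float)
        g = (x / 20.0) ** 3  # monotone cubic on [0, 1]
        B, knots, k = build_monotone_basis(x, 6)
        Braw = _design(x, knots)

        def loss(gam):
            f = Braw @ _beta_from_gamma(gam)
            c = np.mean(g - f)
            return np.sum((g - f - c) ** 2) + 1e-6 * np.sum(np.diff(gam) ** 2)

        res = minimize(loss, np.full(k - 1, -1.0), method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10,
                                "fatol": 1e-14})
        f = Braw @ _beta_from_gamma(res.x)
        f += np.mean(g - f)
        assert np.max(np.abs(f - g)) < 0.01


class TestFit:
    def test_intercept_only_constant_response(self):
        y = np.full(60, 0.2)
        m = ScamRegressor(terms=[]).fit(pd.DataFrame(index=range(60)), y)
        assert np.allclose(m.mu_, 0.2, atol=1e-8)
        assert m.deviance_explained_ == pytest.approx(0.0, abs=1e-6)

    def test_monotone_fit_agrees_with_glm_oracle_on_linear_truth(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        X, y, mu = quasi_data(rng, n=400, trials=2000)
        m = ScamRegressor(
            terms=[TermSpec("x", "smooth_monotone_increasing")]).fit(X, y)
        glm = sm.GLM(y, sm.add_constant(X["x"]),
                     family=sm.families.Binomial()).fit(scale="X2")
        assert np.max(np.abs(m.mu_ - glm.fittedvalues)) < 0.01
        dev_glm = 100 * (1 - glm.deviance / glm.null_deviance)
        assert m.deviance_explained_ == pytest.approx(dev_glm, abs=2.0)
        grid, f = m.partial_effect("x")
        assert np.all(np.diff(f) >= -1e-10)

    def test_shape_constraints_hold_on_wiggly_truth(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.uniform(0, 1, n)
        mu = expit(-1 + 2 * np.sqrt(x))  # concave monotone truth
        y = rng.binomial(100, mu) / 100
        m = ScamRegressor(
            terms=[TermSpec("x", "smooth_monotone_increasing")]).fit(
            pd.DataFrame({"x": x}), y)
        grid, f = m.partial_effect("x", np.linspace(0, 1, 200))
        assert np.all(np.diff(f) >= -1e-10)

    def test_nonnegative_smooth_anchored_at_zero(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.uniform(0, 1, n)
        y = rng.binomial(100, expit(-1 + x)) / 100
        m = ScamRegressor(
            terms=[TermSpec("x", "smooth_nonnegative")]).fit(
            pd.DataFrame({"x": x}), y)
        grid, f = m.partial_effect("x", np.linspace(0, 1, 100))
        assert np.all(f >= -1e-10)

    def test_deviance_invariant_to_row_order_and_rescaling(self):
        rng = np.random.default_rng(4)
        X, y, _ = quasi_data(rng, n=300, trials=100)
        terms = [TermSpec("x", "smooth_monotone_increasing")]
        m1 = ScamRegressor(terms=terms).fit(X, y)
        perm = rng.permutation(len(y))
        m2 = ScamRegressor(terms=terms).fit(X.iloc[perm], y[perm])
        assert m1.deviance_explained_ == pytest.approx(
            m2.deviance_explained_, abs=1e-6)
        m3 = ScamRegressor(terms=terms).fit(
            pd.DataFrame({"x": 3.0 * X["x"] + 7.0}), y)
        assert m1.deviance_explained_ == pytest.approx(
            m3.deviance_explained_, abs=0.1)

    def test_edf_monotone_in_lambda(self):
        rng = np.random.default_rng(3)
        X, y, _ = quasi_data(rng)
        m = ScamRegressor(terms=[TermSpec("x", "smooth_monotone_increasing")],
                          select_lambda=False).fit(X, y)
        edfs = []
        for lg in np.linspace(-2, 4, 13):
            fit = m._fit_fixed_lambda(y, {"x": 10.0 ** lg}, m.theta_)
            edfs.append(fit["edf_total"])
        assert np.all(np.diff(edfs) <= 1e-3)

    def test_factor_and_linear_coefficients(self):
        rng = np.random.default_rng(5)
        n = 600
        grp = rng.choice(["P1P1", "P1P2", "P2P2"], n)
        x = rng.uniform(0, 1, n)
        eta = -2.0 + 0.8 * (grp == "P1P2") - 0.4 * (grp == "P2P2") + 0.5 * x
        y = rng.binomial(200, expit(eta)) / 200
        m = ScamRegressor(terms=[
            TermSpec("clus_type", "factor", ref_level="P1P1"),
            TermSpec("x", "linear")]).fit(
            pd.DataFrame({"clus_type": grp, "x": x}), y)
        assert m.coef_["clus_type"]["P1P2"] == pytest.approx(0.8, abs=0.1)
        assert m.coef_["clus_type"]["P2P2"] == pytest.approx(-0.4, abs=0.1)
        assert m.coef_["x"] == pytest.approx(0.5, abs=0.15)


class TestSklearnProtocol:
    def test_get_params_clone_and_predict(self):
        from sklearn.base import clone
        rng = np.random.default_rng(0)
        X, y, _ = quasi_data(rng, n=200, trials=100)
        est = ScamRegressor(terms=[TermSpec("x", "smooth_monotone_increasing",
                                            k=6)], n_sweeps=1)
        assert est.get_params()["n_sweeps"] == 1
        est2 = clone(est).set_params(n_sweeps=2)
        assert est2.n_sweeps == 2 and est.n_sweeps == 1
        est.fit(X, y)
        Xnew = pd.DataFrame({"x": np.linspace(X["x"].min(), X["x"].max(), 17)})
        mu = est.predict(Xnew)
        assert mu.shape == (17,)
        assert np.all((0 < mu) & (mu < 1))
        assert np.all(np.diff(mu) >= -1e-10)   # monotone in the covariate


class TestDropNullSmooths:
    def test_noise_removed_signal_retained(self):
        removed = kept = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            n = 300
            x = rng.uniform(0, 10, n)
            z = rng.uniform(0, 1, n)
            y = rng.binomial(60, expit(-2 + 0.3 * x)) / 60
            X = pd.DataFrame({"x": x, "z": z})
            terms = [TermSpec("x", "smooth_monotone_increasing"),
                     TermSpec("z", "smooth_monotone_increasing")]
            final, fit = drop_null_smooths(X.assign(fst=y), terms)
            names = [t.name for t in final]
            removed += "z" not in names
            kept += "x" in names
        assert removed >= 18
        assert kept == n_seeds

    def test_all_null_leaves_parametric_only(self):
        rng = np.random.default_rng(0)
        n = 200
        z1, z2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        lin = rng.uniform(0, 1, n)
        y = rng.binomial(80, expit(-1.5 + 0.8 * lin)) / 80
        X = pd.DataFrame({"z1": z1, "z2": z2, "lin": lin, "fst": y})
        terms = [TermSpec("z1", "smooth_monotone_increasing"),
                 TermSpec("z2", "smooth_monotone_increasing"),
                 TermSpec("lin", "linear")]
        final, fit = drop_null_smooths(X, terms)
        assert [t.name for t in final] == ["lin"]


class TestTermTests:
    def test_strong_linear_effect_detected(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.uniform(0, 1, n)
            y = rng.binomial(100, expit(-1 + 1.5 * x)) / 100
            m = ScamRegressor(terms=[TermSpec("x", "linear")]).fit(
                pd.DataFrame({"x": x}), y)
            (tt,) = m.term_tests()
            hits += tt.p_value < 0.001
        assert hits >= int(0.95 * n_seeds)

    def test_smooth_f_test_reports_edf_and_significance(self):
        rng = np.random.default_rng(7)
        X, y, _ = quasi_data(rng, n=500, trials=100)
        m = ScamRegressor(
            terms=[TermSpec("x", "smooth_monotone_increasing")]).fit(X, y)
        (tt,) = m.term_tests()
        assert tt.kind == "smooth_monotone_increasing"
        assert tt.statistic > 0 and tt.p_value < 1e-6
        assert tt.edf == pytest.approx(m.edf_["x"])

    def test_partial_effect_flags_extrapolation(self):
        rng = np.random.default_rng(8)
        X, y, _ = quasi_data(rng, n=200, trials=100)
        m = ScamRegressor(
            terms=[TermSpec("x", "smooth_monotone_increasing")]).fit(X, y)
        with pytest.warns(UserWarning, match="extrapolat"):
            m.partial_effect("x", np.array([-5.0, 5.0, 50.0]))

    def test_saturating_curve_recovered(self):
        # plateau truth: rises to x0=4 then flat
        rng = np.random.default_rng(9)
        n = 600
        x = rng.uniform(0, 10, n)
        f_true = np.minimum(x, 4.0) * 0.5
        y = rng.binomial(150, expit(-2 + f_true)) / 150
        m = ScamRegressor(
            terms=[TermSpec("x", "smooth_monotone_increasing")]).fit(
            pd.DataFrame({"x": x}), y)
        grid = np.linspace(0.2, 9.8, 60)
        _, f = m.partial_effect("x", grid)
        truth_centered = (np.minimum(grid, 4.0) * 0.5
                          - np.mean(np.minimum(x, 4.0) * 0.5))
        f_centered = f - np.mean(m.partial_effect("x", x)[1])
        rmse = np.sqrt(np.mean((f_centered - truth_centered) ** 2))
        assert rmse < 0.1
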