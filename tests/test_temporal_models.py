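import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import venttraits as vt
from venttraits.temporal_models import _newton_multinomial, _saturated_loglik
from venttraits.trait_data import DataError

TIMES7 = np.array([9, 22, 33, 53, 66, 96, 135], dtype=float)


def softmax_probs(beta, times):
    """Independent probability oracle on the month scale."""
    t = np.asarray(times, float)
    eta = beta[:, 0][None, :] + beta[:, 1][None, :] * t[:, None] \
        + beta[:, 2][None, :] * t[:, None] ** 2
    eta = eta - eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    return p / p.sum(axis=1, keepdims=True)


class TestFitMultinomial:
    def test_no_signal_gives_zero_slopes_and_pooled_proportion(self):
        counts = np.tile([30, 10], (5, 1))
        fit = vt.fit_multinomial(counts, [9, 22, 33, 53, 66])
        assert abs(fit.beta["b1"]).max() < 1e-6
        assert abs(fit.beta["b2"]).max() < 1e-6
        np.testing.assert_allclose(fit.fitted.to_numpy(),
                                   np.tile([0.75, 0.25], (5, 1)), atol=1e-6)

    def test_parameter_recovery_at_large_counts(self):
        # planted coefficients, 1e5 individuals per time: estimates should
        # sit within a few asymptotic standard errors of the truth
        beta = np.array([[0.0, 0.0, 0.0],
                         [0.5, 0.02, -1.5e-4],
                         [-0.3, -0.01, 1.0e-4]])
        rng = np.random.default_rng(8)
        P = softmax_probs(beta, TIMES7)
        counts = np.stack([rng.multinomial(100_000, P[i]) for i in range(7)])
        fit = vt.fit_multinomial(pd.DataFrame(counts, columns=list("abc")),
                                 TIMES7, baseline="a")
        est = fit.beta.loc[list("abc")].to_numpy()
        # identifiability: compare contrasts against baseline "a"
        truth = beta - beta[0]
        tol = np.array([0.02, 6e-4, 6e-6])  # ~3 asymptotic SEs per column
        assert (np.abs(est - truth) <= tol).all(), est - truth

    def test_loglik_matches_independent_optimizer_on_tiny_fixture(self):
        counts = np.array([[5, 3, 1], [2, 8, 4], [1, 2, 9]], dtype=float)
        times = np.array([0.0, 1.0, 2.0])
        fit = vt.fit_multinomial(counts, times)

        # independent parameterization and optimizer: BFGS on the raw NLL
        def nll(theta):
            b = np.zeros((3, 3))
            b[1:] = theta.reshape(2, 3)
            p = softmax_probs(b, times)
            return -np.sum(counts * np.log(p))

        best = min(minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10,
                                     "fatol": 1e-12}).fun
                   for x0 in [np.zeros(6), np.ones(6), -np.ones(6)])
        assert fit.loglik == pytest.approx(-best, abs=1e-4)

    def test_baseline_invariance(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(5, 50, size=(5, 4)).astype(float)
        times = TIMES7[:5]
        fits = [vt.fit_multinomial(pd.DataFrame(counts, columns=list("wxyz")),
                                   times, baseline=b) for b in "wxyz"]
        for f in fits[1:]:
            np.testing.assert_allclose(f.fitted.to_numpy(),
                                       fits[0].fitted.to_numpy(), atol=1e-8)
            assert f.deviance == pytest.approx(fits[0].deviance, abs=1e-8)

    def test_deviance_weakly_decreases_with_model_order(self):
        rng = np.random.default_rng(10)
        counts = rng.integers(1, 60, size=(6, 3)).astype(float)
        t = TIMES7[:6]
        z = (t - t.mean()) / t.std()
        devs = []
        for cols in ([np.ones_like(z)],
                     [np.ones_like(z), z],
                     [np.ones_like(z), z, z * z]):
            X = np.column_stack(cols)
            _, ll, *_ = _newton_multinomial(counts, X, baseline=0)
            devs.append(2 * (_saturated_loglik(counts) - ll))
        assert devs[0] >= devs[1] - 1e-8 >= devs[2] - 2e-8

    def test_too_few_times_is_error(self):
        with pytest.raises(DataError, match="distinct times"):
            vt.fit_multinomial(np.array([[1, 2], [3, 4]]), [9, 22])

    def test_empty_categories_dropped_with_warning(self):
        counts = np.array([[5, 0, 3], [6, 0, 2], [7, 0, 1]], dtype=float)
        with pytest.warns(UserWarning, match="empty"):
            fit = vt.fit_multinomial(pd.DataFrame(counts, columns=list("abc")),
                                     [0, 1, 2])
        assert fit.categories == ["a", "c"]

    def test_predict_matches_fitted_at_observed_times(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(5, 40, size=(7, 3)).astype(float)
        fit = vt.fit_multinomial(counts, TIMES7)
        np.testing.assert_allclose(fit.predict(TIMES7).to_numpy(),
                                   fit.fitted.to_numpy(), atol=1e-8)


class TestFitOLSQuadratic:
    def test_exact_parabola_r2_one(self):
        t = TIMES7
        y = 2.0 - 0.1 * t + 0.003 * t * t
        fit = vt.fit_ols_quadratic(y, t)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_values_r2_zero(self):
        fit = vt.fit_ols_quadratic(np.full(7, 3.3), TIMES7)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=7)
        X = np.column_stack([np.ones(7), TIMES7, TIMES7 ** 2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        fit = vt.fit_ols_quadratic(y, TIMES7)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-9)
        assert fit.r2 == pytest.approx(r2, abs=1e-12)
        # residual orthogonality to the design
        assert np.abs(fit.residuals @ X).max() < 1e-8


class TestRandomizationDeviance:
    def sample_data(self, seed=0, trend=False):
        rng = np.random.default_rng(seed)
        times = np.repeat(TIMES7, 4)
        if trend:
            beta = np.array([[0, 0, 0], [2.5, -0.08, 3.5e-4]])
            P = softmax_probs(beta, times)
            counts = np.stack([rng.multinomial(300, P[i])
                               for i in range(len(times))])
        else:
            counts = rng.multinomial(80, [0.5, 0.5], size=len(times))
        return counts, times

    def test_permutation_invariant_data_tie_rules(self):
        times = np.repeat(TIMES7, 2)
        counts = np.tile([7, 3], (len(times), 1))  # identical surfaces
        rt = vt.randomization_test_deviance(counts, times, n_rand=50, seed=0)
        assert np.allclose(rt.null, rt.observed)
        assert rt.p_strict == 0.0  # strict rule degenerates to 0 under ties
        assert rt.p_smoothed == 1.0  # smoothed rule counts the ties

    def test_reproducible_given_seed(self):
        counts, times = self.sample_data(3)
        a = vt.randomization_test_deviance(counts, times, n_rand=30, seed=7)
        b = vt.randomization_test_deviance(counts, times, n_rand=30, seed=7)
        np.testing.assert_array_equal(a.null, b.null)
        assert a.p_smoothed == b.p_smoothed

    def test_power_against_planted_trend(self):
        hits = 0
        for seed in range(20):
            counts, times = self.sample_data(seed, trend=True)
            rt = vt.randomization_test_deviance(counts, times, n_rand=199,
                                                seed=seed)
            hits += rt.p_smoothed <= 0.01
        assert hits >= 19  # strong planted quadratic trend detected

    def test_category_relabeling_invariance(self):
        counts, times = self.sample_data(4, trend=True)
        a = vt.randomization_test_deviance(counts, times, n_rand=60, seed=1)
        b = vt.randomization_test_deviance(counts[:, ::-1], times, n_rand=60,
                                           seed=1)
        np.testing.assert_allclose(a.null, b.null, atol=1e-6)
        assert a.p_smoothed == b.p_smoothed

    def test_time_affine_rescaling_invariance(self):
        counts, times = self.sample_data(5, trend=True)
        a = vt.randomization_test_deviance(counts, times, n_rand=60, seed=2)
        b = vt.randomization_test_deviance(counts, 2.0 * times + 7.0,
                                           n_rand=60, seed=2)
        np.testing.assert_allclose(a.null, b.null, atol=1e-6)
        assert a.p_smoothed == b.p_smoothed

    def test_fewer_samples_than_times_is_error(self):
        with pytest.raises(DataError):
            vt.randomization_test_deviance(np.ones((2, 2)), [1, 2, 3][:2],
                                           n_rand=9, seed=0)


class TestRandomizationR2:
    def test_perfect_parabola_tie_rules(self):
        y = 1.0 + 0.5 * TIMES7 - 0.002 * TIMES7 ** 2
        rt = vt.randomization_test_r2(y, TIMES7, n_rand=99, seed=0)
        assert rt.observed == pytest.approx(1.0)
        assert rt.p_strict == 0.0
        assert rt.p_smoothed <= (1 + 99 * 0.02) / 100  # ~1/(n+1) up to ties

    def test_reproducible_and_tie_stable(self):
        y = np.array([1.0, 2.0, 2.0, 3.0, 1.0, 2.0, 4.0])
        a = vt.randomization_test_r2(y, TIMES7, n_rand=50, seed=3)
        b = vt.randomization_test_r2(y, TIMES7, n_rand=50, seed=3)
        np.testing.assert_array_equal(a.null, b.null)
        # exchanging two equal values leaves R2 unchanged
        y2 = y.copy()
        y2[1], y2[2] = y2[2], y2[1]
        c = vt.randomization_test_r2(y2, TIMES7, n_rand=50, seed=3)
        assert c.observed == pytest.approx(a.observed)

    def test_null_matches_per_permutation_ols(self):
        rng = np.random.default_rng(13)
        y = rng.normal(size=7)
        rt = vt.randomization_test_r2(y, TIMES7, n_rand=20, seed=5)
        # replay the same permutations through the scalar OLS path
        rng2 = np.random.default_rng(5)
        for r in range(20):
            perm = y[rng2.permutation(7)]
            assert rt.null[r] == pytest.approx(
                vt.fit_ols_quadratic(perm, TIMES7).r2, abs=1e-10)


class TestTrendReport:
    def test_single_category_trait_skipped(self, toy_specs):
        data = pd.DataFrame({"size": ["small", "small"],
                             "feeding": ["grazer", "grazer"]},
                            index=["sp1", "sp2"])
        traits = vt.TraitTable(data, toy_specs)
        from conftest import make_abundance
        table = make_abundance([9, 22, 33, 53], np.ones((4, 2), dtype=int),
                               ["sp1", "sp2"])
        labels = pd.Series([0, 1], index=["sp1", "sp2"])
        div = pd.DataFrame({"hill_species": [1.5, 1.4, 1.6, 1.3]},
                           index=pd.Index([9.0, 22.0, 33.0, 53.0],
                                          name="time_months"))
        rep = vt.trend_report(table, traits, toy_specs, labels, div,
                              n_rand=19, seed=0)
        row = rep[rep.unit == "size"].iloc[0]
        assert "skipped" in row["note"]
        assert np.isnan(row["observed"])

    def test_report_schema_and_reproducibility(self, reference_run):
        rep = reference_run["trends"]
        expected_cols = {"unit", "statistic_name", "observed", "p_strict",
                         "p_smoothed", "n_rand", "seed", "converged", "note"}
        assert expected_cols <= set(rep.columns)
        assert ((rep["p_smoothed"].dropna() >= 0)
                & (rep["p_smoothed"].dropna() <= 1)).all()
        # 8 traits + guilds + 3 diversity metrics + RaoQ sensitivity row
        assert len(rep) == 13
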