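"""Beta regression, OLS, Wald tests and marginal-means contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from accethogram.inferstats import (
    RegressionDesign,
    fit_beta_regression,
    fit_ols,
    pairwise_contrasts,
    squeeze_proportions,
    wald_tests,
)


def _beta_sample(mu, phi, n, rng):
    return rng.beta(mu * phi, (1 - mu) * phi, size=n)


def _oracle_betareg(X, y):
    """Independent direct optimiser of the beta log-likelihood (mean model
    on the logit link, log-precision), used as the cross-check oracle."""

    def nll(params):
        beta, logphi = params[:-1], params[-1]
        mu = special.expit(X @ beta)
        phi = np.exp(logphi)
        a, b = mu * phi, (1 - mu) * phi
        return -np.sum(stats.beta.logpdf(y, a, b))

    # logit-least-squares start
    start = np.append(np.linalg.lstsq(X, special.logit(y), rcond=None)[0], 1.0)
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x


class TestBetaRegression:
    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(0)
        y = _beta_sample(0.8, 50, 2000, rng)
        fit = fit_beta_regression(RegressionDesign("y", "1"), pd.DataFrame({"y": y}))
        mu_hat = special.expit(fit.beta["Intercept"])
        assert fit.converged
        assert mu_hat == pytest.approx(0.8, abs=0.02)
        assert fit.phi == pytest.approx(50, rel=0.15)

    def test_nested_loglik_monotone(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 300)
        mu = special.expit(-0.3 + 0.6 * x)
        y = _beta_sample(mu, 30, 300, rng)
        df = pd.DataFrame({"y": y, "x": x})
        ll_null = fit_beta_regression(RegressionDesign("y", "1"), df).loglik
        ll_full = fit_beta_regression(RegressionDesign("y", "x"), df).loglik
        assert ll_full >= ll_null

    def test_small_instance_matches_oracle(self):
        """n=12, two mean coefficients: MLE agrees with a direct
        Nelder-Mead optimisation of the likelihood to 1e-4."""
        rng = np.random.default_rng(2)
        x = np.repeat([0.0, 1.0], 6)
        y = _beta_sample(special.expit(0.4 + 0.5 * x), 25, 12, rng)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_beta_regression(RegressionDesign("y", "x"), df)
        X = np.column_stack([np.ones(12), x])
        oracle = _oracle_betareg(X, y)
        assert fit.beta.to_numpy() == pytest.approx(oracle[:2], abs=1e-4)
        assert np.log(fit.phi) == pytest.approx(oracle[2], abs=1e-3)

    def test_boundary_squeeze(self):
        y = np.array([0.0, 0.5, 1.0, 0.7, 0.9, 0.8, 0.2, 0.6])
        sq = squeeze_proportions(y)
        assert np.all((sq > 0) & (sq < 1))
        fit = fit_beta_regression(
            RegressionDesign("y", "1"), pd.DataFrame({"y": y})
        )
        assert np.isfinite(fit.loglik)

    def test_vcov_symmetric_psd(self):
        rng = np.random.default_rng(3)
        y = _beta_sample(0.7, 20, 100, rng)
        fit = fit_beta_regression(RegressionDesign("y", "1"), pd.DataFrame({"y": y}))
        V = fit.vcov.to_numpy()
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) > -1e-12)


class TestWald:
    def test_z_and_p_arithmetic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        y = _beta_sample(special.expit(0.3 + 0.0 * x), 40, 500, rng)
        fit = fit_beta_regression(RegressionDesign("y", "x"), pd.DataFrame({"y": y, "x": x}))
        tab = wald_tests(fit)
        row = tab[tab["term"] == "x"].iloc[0]
        assert row["z"] == pytest.approx(row["estimate"] / row["se"])
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(row["z"])), abs=1e-12)

    def test_null_coefficient_type_I_error(self):
        """With a true-zero coefficient, the Wald P < 0.05 rate over seeded
        replicates sits near the nominal 5%."""
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.integers(0, 2, 120).astype(float)
            y = _beta_sample(0.7, 30, 120, rng)
            fit = fit_beta_regression(
                RegressionDesign("y", "x"), pd.DataFrame({"y": y, "x": x})
            )
            p = wald_tests(fit).set_index("term").loc["x", "p"]
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.035)


class TestContrasts:
    def _fit(self, levels, mus, n_per=40, phi=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for lev, mu in zip(levels, mus):
            rows.append(pd.DataFrame({"y": _beta_sample(mu, phi, n_per, rng), "g": lev}))
        df = pd.concat(rows, ignore_index=True)
        return fit_beta_regression(RegressionDesign("y", "g"), df)

    def test_two_levels_one_contrast(self):
        fit = self._fit(["a", "b"], [0.6, 0.8])
        cons = pairwise_contrasts(fit, "g")
        assert len(cons) == 1
        assert cons[0].contrast == "a - b"
        assert cons[0].estimate < 0

    def test_three_levels_three_contrasts_and_cycle(self):
        fit = self._fit(["none", "scute1", "scute3"], [0.5, 0.7, 0.6])
        cons = pairwise_contrasts(fit, "g")
        assert len(cons) == 3
        by = {c.contrast: c.estimate for c in cons}
        # (a-b) + (b-c) - (a-c) = 0 over the closed cycle of levels
        cycle = by["none - scute1"] + by["scute1 - scute3"] - by["none - scute3"]
        assert cycle == pytest.approx(0.0, abs=1e-10)

    def test_label_swap_antisymmetry(self):
        fit_ab = self._fit(["a", "b"], [0.6, 0.8], seed=7)
        fit_ba = self._fit(["b", "a"], [0.6, 0.8], seed=7)
        c_ab = pairwise_contrasts(fit_ab, "g")[0]
        c_ba = pairwise_contrasts(fit_ba, "g")[0]
        # tolerance bounded by optimiser convergence, not exact arithmetic
        assert c_ab.estimate == pytest.approx(-c_ba.estimate, abs=1e-5)
        assert c_ab.p_value == pytest.approx(c_ba.p_value, abs=1e-5)

    def test_single_level_rejected(self):
        fit = self._fit(["a", "b"], [0.6, 0.8])
        with pytest.raises(ValueError, match="levels"):
            pairwise_contrasts(fit, "g", at={"g": "a"})


class TestOls:
    def test_exact_linear_data(self):
        u = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 1.2])
        df = pd.DataFrame({"cd": 0.02 + 0.005 * u, "velocity": u})
        fit = fit_ols(RegressionDesign("cd", "velocity"), df)
        assert fit.beta["Intercept"] == pytest.approx(0.02, abs=1e-12)
        assert fit.beta["velocity"] == pytest.approx(0.005, abs=1e-12)
        assert fit._res.resid.to_numpy() == pytest.approx(np.zeros(6), abs=1e-12)

    def test_slope_recovery_within_2se(self):
        """Known per-position slopes recovered within 2 SE in ~95% of
        seeded replicates."""
        rng = np.random.default_rng(8)
        ok = 0
        reps = 100
        for _ in range(reps):
            u = np.tile([0.2, 0.4, 0.6, 0.8, 1.0, 1.2], 4)
            y = 0.03 + 0.007 * u + rng.normal(0, 0.002, len(u))
            fit = fit_ols(
                RegressionDesign("cd", "velocity"),
                pd.DataFrame({"cd": y, "velocity": u}),
            )
            se = np.sqrt(fit.vcov.loc["velocity", "velocity"])
            ok += abs(fit.beta["velocity"] - 0.007) <= 2 * se
        assert ok >= 88  # binomial(100, .95) lower tail

    def test_rank_deficiency_raises(self):
        df = pd.DataFrame(
            {"cd": [0.1, 0.2, 0.3, 0.4], "position": ["a"] * 4,
             "velocity": [0.2, 0.4, 0.6, 0.8]}
        )
        with pytest.raises(ValueError):
            fit_ols(RegressionDesign("cd", "position * velocity"), df)
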