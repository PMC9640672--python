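import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from urbanbees.alpha import (
    _laplace_loglik,
    _penalized_newton,
    _ztnb_eta_derivs,
    check_collinearity,
    fit_richness_model,
    lrt,
    morans_i,
    nb_loglik,
    ztnb_loglik,
    ztnb_sample,
)
from urbanbees.core import FitResult
from urbanbees.synthetic import generate_sites, scenario, simulate_richness


def _sites_frame(n, seed=0, categories=2):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "site_id": [f"s{i}" for i in range(n)],
            "x": rng.uniform(0, 10_000, n),
            "y": rng.uniform(0, 10_000, n),
            "pop_density": rng.gamma(2, 500, n),
            "impervious_pct": rng.uniform(0, 100, n),
            "region": rng.choice(["Atlantic", "Continental"], n),
            "active_days": rng.integers(1, 10, n),
            "passive_hours": rng.gamma(2, 10, n),
            "kick_net": rng.integers(0, 2, n),
            "sampling_category": [f"C{i % categories}" for i in range(n)],
        }
    )


class TestZtnbLikelihood:
    def test_truncation_identity(self, rng):
        # truncated ll == untruncated ll - log(1 - P0), for random draws
        for _ in range(20):
            theta = rng.uniform(0.3, 8.0)
            eta = rng.normal(0, 1.5, size=10)
            y = rng.integers(1, 30, size=10).astype(float)
            mu = np.exp(eta)
            p0 = (theta / (theta + mu)) ** theta
            expected = nb_loglik(y, eta, theta) - np.log(1 - p0)
            np.testing.assert_allclose(ztnb_loglik(y, eta, theta), expected, rtol=1e-10)

    def test_analytic_derivatives_match_numeric(self, rng):
        theta = 1.7
        eta = rng.normal(0.5, 1.0, size=15)
        y = rng.integers(1, 20, size=15).astype(float)
        _, grad, w = _ztnb_eta_derivs(y, eta, theta)
        h = 1e-6
        num_grad = (ztnb_loglik(y, eta + h, theta) - ztnb_loglik(y, eta - h, theta)) / (2 * h)
        np.testing.assert_allclose(grad, num_grad, rtol=1e-5, atol=1e-7)
        gp = _ztnb_eta_derivs(y, eta + h, theta)[1]
        gm = _ztnb_eta_derivs(y, eta - h, theta)[1]
        np.testing.assert_allclose(w, -(gp - gm) / (2 * h), rtol=1e-4, atol=1e-6)

    def test_sampler_never_returns_zero(self, rng):
        draws = ztnb_sample(np.full(500, 0.3), 0.8, rng)
        assert (draws >= 1).all()


class TestFitAgainstOracles:
    def test_intercept_only_matches_direct_maximization(self):
        rng = np.random.default_rng(7)
        y = ztnb_sample(np.full(50, 6.0), 2.0, rng)

        # independent oracle: direct 2-parameter numerical maximization
        def nll(params):
            return -ztnb_loglik(y.astype(float), np.full(len(y), params[0]), np.exp(params[1])).sum()

        oracle = optimize.minimize(nll, [np.log(y.mean()), 0.0], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12})
        sites = _sites_frame(50)
        fit = fit_richness_model(
            sites, y, formula_spec=(), spatial=False, category_effect=False
        )
        assert fit.converged
        assert fit.coefficient("(Intercept)")["estimate"] == pytest.approx(
            oracle.x[0], abs=1e-4
        )
        assert fit.loglik == pytest.approx(-oracle.fun, abs=1e-6)

    def test_laplace_matches_gauss_hermite_on_tiny_nested_case(self):
        # single random intercept, 2 groups, small counts
        rng = np.random.default_rng(21)
        n = 16
        sites = _sites_frame(n, seed=3, categories=2)
        cat = np.array([i % 2 for i in range(n)])
        b_true = np.array([0.15, -0.15])
        y = ztnb_sample(np.exp(2.0 + b_true[cat]), 3.0, rng)

        nodes, weights = np.polynomial.hermite_e.hermegauss(60)

        def gh_marginal_nll(params):
            beta0, log_theta, log_s2 = params
            theta, sd = np.exp(log_theta), np.exp(0.5 * log_s2)
            total = 0.0
            for g in (0, 1):
                yg = y[cat == g].astype(float)
                lls = np.array([
                    ztnb_loglik(yg, np.full(len(yg), beta0 + sd * u), theta).sum()
                    for u in nodes
                ])
                total += np.log((weights * np.exp(lls - lls.max())).sum()) + lls.max() \
                    - np.log(np.sqrt(2 * np.pi))
            return -total

        oracle = optimize.minimize(
            gh_marginal_nll, [2.0, 1.0, np.log(0.05)], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        fit = fit_richness_model(
            sites, y, formula_spec=(), spatial=False, category_effect=True
        )
        assert fit.coefficient("(Intercept)")["estimate"] == pytest.approx(
            oracle.x[0], abs=1e-3
        )

    def test_spatial_variance_zero_equals_nonspatial_loglik(self):
        rng = np.random.default_rng(5)
        sites = _sites_frame(40, seed=9)
        y = ztnb_sample(np.full(40, 8.0), 2.5, rng).astype(float)
        x_mat = np.ones((40, 1))
        theta = 2.5

        coef_ns, _, _, ok_ns = _penalized_newton(y, x_mat, np.zeros(1), np.array([2.0]), theta)
        ll_ns = _laplace_loglik(y, x_mat, np.zeros(1), coef_ns, theta, 1)

        # append a spatial block with its variance pinned to ~0
        xy = sites[["x", "y"]].to_numpy()
        d = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
        chol = np.linalg.cholesky(np.exp(-d / 1000.0) + 1e-8 * np.eye(40))
        m_mat = np.hstack([x_mat, chol])
        dinv = np.r_[0.0, np.full(40, 1e12)]
        coef_sp, _, _, ok_sp = _penalized_newton(
            y, m_mat, dinv, np.r_[2.0, np.zeros(40)], theta
        )
        ll_sp = _laplace_loglik(y, m_mat, dinv, coef_sp, theta, 1)
        assert ok_ns and ok_sp
        assert ll_sp == pytest.approx(ll_ns, abs=1e-6)

    def test_zero_richness_rejected(self):
        sites = _sites_frame(10)
        with pytest.raises(ValueError, match="richness"):
            fit_richness_model(sites, [0] + [3] * 9, spatial=False)


class TestSimulationBehaviour:
    def test_parameter_recovery_negative_impervious_effect(self):
        cfg = scenario("null", seed=17, n_sites=400)
        sites = generate_sites(cfg)
        hits = 0
        reps = 6
        for k in range(reps):
            y = simulate_richness(sites, beta_imp=-0.3, seed=100 + k)
            fit = fit_richness_model(
                sites, y, spatial=False, label=f"rep{k}"
            )
            row = fit.coefficient("impervious_pct")
            if row["estimate"] < 0 and abs(row["estimate"] + 0.3) <= 2 * row["se"]:
                hits += 1
        assert hits >= reps - 1


class TestLrt:
    def _fit(self, terms, ll):
        coef = pd.DataFrame({"term": terms, "estimate": 0.0, "se": 1.0, "z": 0.0, "p": 1.0})
        return FitResult(label="x", coef=coef, loglik=ll, converged=True)

    def test_identical_fits(self):
        full = self._fit(["a", "b"], -100.0)
        red = self._fit(["a"], -100.0)
        chi2, df, p = lrt(full, red)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_worked_chi2_tail(self):
        chi2, df, p = lrt(self._fit(["a", "b"], -100.0), self._fit(["a"], -102.0))
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-10)
        assert p == pytest.approx(0.0455, abs=1e-3)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fit(["a"], -100.0), self._fit(["a", "b"], -99.0))

    def test_negative_chi2_clipped(self):
        chi2, _, p = lrt(self._fit(["a", "b"], -101.0), self._fit(["a"], -100.0))
        assert chi2 == 0.0 and p == 1.0


class TestMoransI:
    def test_alternating_line_negative_autocorrelation(self):
        coords = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        res = morans_i([1, -1, 1, -1], coords, {"k": 1})
        assert res.i < res.expected

    def test_smooth_gradient_positive(self):
        gx, gy = np.meshgrid(np.arange(5.0), np.arange(5.0))
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        res = morans_i(gx.ravel() + gy.ravel(), coords, {"k": 4})
        assert res.i > 0 and res.p < 0.05

    def test_permutation_null_mean(self, rng):
        gx, gy = np.meshgrid(np.arange(5.0), np.arange(5.0))
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        base = rng.normal(size=25)
        sims = [
            morans_i(rng.permutation(base), coords, {"k": 4}).i for _ in range(100)
        ]
        assert np.mean(sims) == pytest.approx(-1 / 24, abs=0.05)

    def test_constant_residuals_rejected(self):
        coords = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            morans_i([2.0, 2.0, 2.0], coords)


class TestCollinearity:
    def test_orthogonal(self):
        r, vif = check_collinearity([1, -1, 1, -1], [1, 1, -1, -1])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert vif == pytest.approx(1.0)

    def test_paper_magnitude(self, rng):
        # r = 0.62 -> VIF = 1 / (1 - 0.62^2) ~ 1.625
        x = rng.normal(size=20_000)
        y = 0.62 * x + np.sqrt(1 - 0.62**2) * rng.normal(size=20_000)
        r, vif = check_collinearity(x, y)
        assert vif == pytest.approx(1 / (1 - r * r), rel=1e-12)
        assert vif == pytest.approx(1.625, abs=0.05)

    def test_identical_vectors_flagged(self, rng):
        x = rng.normal(size=10)
        with pytest.warns(UserWarning, match="collinearity"):
            r, vif = check_collinearity(x, x)
        assert vif == np.inf and r == pytest.approx(1.0)
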