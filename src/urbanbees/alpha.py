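"""Zero-truncated negative-binomial richness regression.

The model is a log-link NB2 regression conditioned on positivity,
``P(Y=y | Y>0) = NB(y; mu, theta) / (1 - (theta/(theta+mu))^theta)``,
with an optional Gaussian random intercept per sampling category and an
optional Gaussian spatial random effect with exponential correlation
``exp(-d / rho)``.  Random effects are integrated out by a Laplace
approximation at the joint mode (penalized Newton inner loop); the
dispersion and variance parameters are maximized by a derivative-free
outer optimizer, with the spatial range ``rho`` profiled over a
log-spaced grid.

Also provides the likelihood-ratio test between nested fits, Moran's I
residual diagnostics, and the collinearity (VIF) screen for the two
urbanization metrics.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core.types import FitResult, LRTRecord, MoranResult
from .preprocess import log_density

logger = logging.getLogger(__name__)

_WMIN = 1e-10


# ---------------------------------------------------------------------------
# zero-truncated NB likelihood pieces


def nb_loglik(y, eta, theta):
    """Untruncated NB2 log-pmf with log link, elementwise."""
    y = np.asarray(y, dtype=float)
    mu = np.exp(eta)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta)
        + y * eta
        - (y + theta) * np.log(theta + mu)
    )


def ztnb_loglik(y, eta, theta):
    """Zero-truncated NB2 log-pmf: NB log-pmf minus ``log(1 - P0)``."""
    mu = np.exp(eta)
    log_p0 = theta * (np.log(theta) - np.log(theta + mu))
    return nb_loglik(y, eta, theta) - np.log1p(-np.exp(log_p0))


def _ztnb_eta_derivs(y, eta, theta):
    """(loglik, d/d eta, -d2/d eta2) of the truncated log-pmf, elementwise."""
    y = np.asarray(y, dtype=float)
    mu = np.exp(eta)
    p0 = np.exp(theta * (np.log(theta) - np.log(theta + mu)))
    om = 1.0 - p0
    s = theta * mu / (theta + mu)
    ll = nb_loglik(y, eta, theta) - np.log(om)
    grad = y - (y + theta) * mu / (theta + mu) - p0 * s / om
    # curvature: d/d eta of the two mean terms plus the truncation term
    p0d = -p0 * s
    sd = s * theta / (theta + mu)
    t_deriv = (p0d * s + p0 * sd) / om + (p0 * s * p0d) / om**2
    w = (y + theta) * theta * mu / (theta + mu) ** 2 + t_deriv
    return ll, grad, np.maximum(w, _WMIN)


def ztnb_sample(mu, theta, rng: np.random.Generator, max_tries: int = 1000):
    """Draw zero-truncated NB2 variates by rejection of zeros."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    out = np.zeros(mu.shape, dtype=np.int64)
    pending = np.ones(mu.shape, dtype=bool)
    for _ in range(max_tries):
        if not pending.any():
            break
        m = mu[pending]
        p = theta / (theta + m)
        draw = rng.negative_binomial(theta, p)
        out[np.flatnonzero(pending)[draw > 0]] = draw[draw > 0]
        nxt = pending.copy()
        nxt[np.flatnonzero(pending)[draw > 0]] = False
        pending = nxt
    if pending.any():
        raise RuntimeError("zero-truncated sampling did not terminate")
    return out


# ---------------------------------------------------------------------------
# Laplace inner/outer machinery


def _penalized_newton(y, m_mat, dinv, coef0, theta, tol=1e-6, max_iter=200):
    """Maximize sum ztnb_ll(eta) - 0.5 coef' Dinv coef, eta = M coef.

    ``dinv`` is the diagonal of the penalty (0 for fixed effects).
    Returns (coef, penalized objective, W at optimum, converged).
    """
    coef = coef0.copy()
    eta = m_mat @ coef

    def objective(c, e):
        ll = ztnb_loglik(y, e, theta)
        return float(ll.sum() - 0.5 * (dinv * c * c).sum())

    obj = objective(coef, eta)
    w = None
    for _ in range(max_iter):
        _, grad, w = _ztnb_eta_derivs(y, eta, theta)
        score = m_mat.T @ grad - dinv * coef
        hess = (m_mat.T * w) @ m_mat
        hess[np.diag_indices_from(hess)] += dinv + 1e-10
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            return coef, obj, w, False
        # step halving to guarantee ascent
        t = 1.0
        for _ in range(40):
            cand = coef + t * step
            eta_c = m_mat @ cand
            obj_c = objective(cand, eta_c)
            if np.isfinite(obj_c) and obj_c >= obj - 1e-12:
                break
            t *= 0.5
        else:
            return coef, obj, w, False
        improved = obj_c - obj
        coef, eta, obj = cand, eta_c, obj_c
        if abs(improved) < tol:
            return coef, obj, w, True
    return coef, obj, w, False


def _laplace_loglik(y, m_mat, dinv, coef, theta, n_fixed):
    """Laplace-approximate marginal log-likelihood at the joint mode."""
    eta = m_mat @ coef
    ll = ztnb_loglik(y, eta, theta).sum()
    pen = 0.5 * (dinv * coef * coef).sum()
    q = len(coef) - n_fixed
    if q == 0:
        return float(ll)
    _, _, w = _ztnb_eta_derivs(y, eta, theta)
    z_mat = m_mat[:, n_fixed:]
    h_bb = (z_mat.T * w) @ z_mat
    h_bb[np.diag_indices_from(h_bb)] += dinv[n_fixed:]
    # -0.5 log|D H| computed as |I + D Z'WZ| for sigma->0 stability
    d_h = h_bb / dinv[n_fixed:, None]
    sign, logdet = np.linalg.slogdet(d_h)
    if sign <= 0:
        return -np.inf
    return float(ll - pen - 0.5 * logdet)


def _exp_corr_chol(xy: np.ndarray, rho: float) -> np.ndarray:
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    corr = np.exp(-d / rho)
    corr[np.diag_indices_from(corr)] += 1e-8
    return np.linalg.cholesky(corr)


def standardize_urbanization(sites: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """``log(x+1)``-transform density, then z-score both metrics."""
    out = sites.copy()
    ld = log_density(out["pop_density"].to_numpy(dtype=float))
    imp = out["impervious_pct"].to_numpy(dtype=float)
    scaling = {}
    for name, vec in (("pop_density", ld), ("impervious_pct", imp)):
        mu, sd = float(np.mean(vec)), float(np.std(vec))
        sd = sd if sd > 0 else 1.0
        out[name + "_std"] = (vec - mu) / sd
        scaling[name] = {"mean": mu, "sd": sd}
    return out, scaling


def _build_design(
    sites: pd.DataFrame, terms: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(sites))], ["(Intercept)"]
    for term in terms:
        if term in ("pop_density", "impervious_pct"):
            cols.append(sites[term + "_std"].to_numpy(dtype=float))
            names.append(term)
        elif term == "region":
            levels = sorted(sites["region"].unique())
            for lev in levels[1:]:
                cols.append((sites["region"] == lev).to_numpy(dtype=float))
                names.append(f"region[{lev}]")
        else:
            raise ValueError(f"unknown term {term!r}")
    return np.column_stack(cols), names


DEFAULT_TERMS = ("pop_density", "impervious_pct", "region")


def fit_richness_model(
    grouped_sites: pd.DataFrame,
    richness: Sequence[int],
    formula_spec: Sequence[str] = DEFAULT_TERMS,
    spatial: bool = True,
    category_effect: bool = True,
    rho_grid: Sequence[float] | None = None,
    lrt_terms: Sequence[str] | None = None,
    seed: int = 0,
    label: str | None = None,
) -> FitResult:
    """Fit the zero-truncated NB richness model.

    ``formula_spec`` names the fixed-effect terms (subset of
    ``pop_density``, ``impervious_pct``, ``region``); continuous terms
    are standardized internally.  ``category_effect`` adds the
    sampling-category random intercept, ``spatial`` the exponential
    spatial random effect with range profiled over ``rho_grid``
    (default: 8 log-spaced values spanning the coordinate range).
    ``lrt_terms`` triggers one likelihood-ratio test per named term by
    refitting without it.
    """
    y = np.asarray(richness, dtype=float)
    if (y < 1).any():
        raise ValueError("richness must be >= 1 everywhere (zero-truncated model)")
    sites, scaling = standardize_urbanization(grouped_sites)
    x_mat, names = _build_design(sites, formula_spec)
    n, p = x_mat.shape

    blocks: list[np.ndarray] = []
    block_names: list[str] = []
    if category_effect:
        if "sampling_category" not in sites.columns or sites["sampling_category"].isna().any():
            raise ValueError("category_effect requires a sampling_category column")
        cats = pd.Categorical(sites["sampling_category"])
        if len(cats.categories) < 2:
            raise ValueError("need >= 2 sampling categories for the random intercept")
        z_cat = np.zeros((n, len(cats.categories)))
        z_cat[np.arange(n), cats.codes] = 1.0
        blocks.append(z_cat)
        block_names.append("sampling_category")

    xy = sites[["x", "y"]].to_numpy(dtype=float)
    if spatial:
        if rho_grid is None:
            span = max(np.ptp(xy[:, 0]), np.ptp(xy[:, 1]), 1.0)
            rho_grid = np.geomspace(span / 50, span, 8)
    else:
        rho_grid = [None]

    best = None
    for rho in rho_grid:
        eff_blocks = list(blocks)
        eff_names = list(block_names)
        if rho is not None:
            eff_blocks.append(_exp_corr_chol(xy, float(rho)))
            eff_names.append("spatial")
        q_sizes = [b.shape[1] for b in eff_blocks]
        m_mat = np.hstack([x_mat] + eff_blocks) if eff_blocks else x_mat
        n_var = len(eff_blocks)

        coef_warm = np.concatenate([
            np.r_[np.log(max(y.mean(), 1.1)), np.zeros(p - 1)],
            np.zeros(sum(q_sizes)),
        ])

        def neg_laplace(psi, _state={"coef": coef_warm}):
            theta = float(np.exp(psi[0]))
            if not (1e-3 < theta < 1e5):
                return 1e10
            dinv = np.zeros(m_mat.shape[1])
            pos = p
            for k, qs in enumerate(q_sizes):
                var = float(np.exp(psi[1 + k]))
                dinv[pos : pos + qs] = 1.0 / max(var, 1e-10)
                pos += qs
            coef, _, _, ok = _penalized_newton(y, m_mat, dinv, _state["coef"], theta)
            if not ok:
                return 1e10
            _state["coef"] = coef
            ll = _laplace_loglik(y, m_mat, dinv, coef, theta, p)
            return -ll if np.isfinite(ll) else 1e10

        psi0 = np.r_[np.log(1.5), np.full(n_var, np.log(0.1))]
        res = optimize.minimize(
            neg_laplace,
            psi0,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 600},
        )
        if best is None or -res.fun > best["ll"]:
            best = {
                "ll": float(-res.fun),
                "psi": res.x,
                "rho": rho,
                "m_mat": m_mat,
                "q_sizes": q_sizes,
                "eff_names": eff_names,
                "success": bool(res.success) or res.fun < 1e9,
            }

    assert best is not None
    theta = float(np.exp(best["psi"][0]))
    dinv = np.zeros(best["m_mat"].shape[1])
    variances = {}
    pos = p
    warns: list[str] = []
    for k, qs in enumerate(best["q_sizes"]):
        var = float(np.exp(best["psi"][1 + k]))
        variances[best["eff_names"][k]] = var
        dinv[pos : pos + qs] = 1.0 / max(var, 1e-10)
        pos += qs
    coef0 = np.zeros(best["m_mat"].shape[1])
    coef0[0] = np.log(max(y.mean(), 1.1))
    coef, _, w, ok = _penalized_newton(y, best["m_mat"], dinv, coef0, theta)
    converged = ok and best["success"]
    if theta > 1e4 or theta < 2e-3:
        warns.append(f"dispersion theta driven to boundary ({theta:.3g})")

    hess = (best["m_mat"].T * w) @ best["m_mat"]
    hess[np.diag_indices_from(hess)] += dinv + 1e-10
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))
    if converged and (se <= 0).any():
        warns.append("non-positive standard error at the optimum")
    est = coef[:p]
    zval = np.divide(est, se, out=np.full(p, np.nan), where=se > 0)
    pval = 2 * stats.norm.sf(np.abs(zval))

    table = pd.DataFrame(
        {"term": names, "estimate": est, "se": se, "z": zval, "p": pval}
    )
    result = FitResult(
        label=label or ("ztnb_spatial" if spatial else "ztnb"),
        coef=table,
        loglik=best["ll"],
        converged=converged,
        variance_components={**variances, "theta": theta, "spatial_range": best["rho"]},
        n_obs=n,
        warnings=warns,
        metadata={
            "formula": list(formula_spec),
            "scaling": scaling,
            "seed": seed,
            "spatial": spatial,
        },
    )
    if not converged:
        logger.warning("fit_richness_model: non-convergence flagged (%s)", result.label)

    if lrt_terms:
        for term in lrt_terms:
            reduced_terms = [t for t in formula_spec if t != term]
            reduced = fit_richness_model(
                grouped_sites,
                richness,
                formula_spec=reduced_terms,
                spatial=spatial,
                category_effect=category_effect,
                rho_grid=rho_grid if spatial else None,
                seed=seed,
                label=f"reduced[-{term}]",
            )
            result.lrt.append(_lrt_record(result, reduced, term))
    return result


def _count_fixed_terms(fit: FitResult) -> int:
    return len(fit.coef)


def _lrt_record(full: FitResult, reduced: FitResult, term: str) -> LRTRecord:
    chi2, df, p = lrt(full, reduced)
    return LRTRecord(term=term, chi2=chi2, df=df, p=p)


def lrt(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: ``chi2 = 2 (ll_f - ll_r)``."""
    full_terms = set(full.coef["term"])
    red_terms = set(reduced.coef["term"])
    if not red_terms.issubset(full_terms):
        raise ValueError("models are not nested (reduced has terms absent from full)")
    df = len(full_terms) - len(red_terms)
    if df < 1:
        raise ValueError("reduced model must drop at least one fixed-effect term")
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged for a valid LRT")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return float(chi2), int(df), p


# ---------------------------------------------------------------------------
# diagnostics


def _moran_weights(
    coords: np.ndarray, k: int = 10, cutoff: float | None = None
) -> np.ndarray:
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    w = 1.0 / d
    if cutoff is not None:
        w[d > cutoff] = 0.0
    if k is not None and k < n - 1:
        order = np.argsort(d, axis=1)
        mask = np.zeros_like(w, dtype=bool)
        rows = np.repeat(np.arange(n), k)
        mask[rows, order[:, :k].ravel()] = True
        w[~mask] = 0.0
    return w


def morans_i(
    residuals: Sequence[float],
    coordinates: np.ndarray,
    weight_spec: dict | None = None,
) -> MoranResult:
    """Moran's I of residuals with a normal-approximation p-value.

    Default weights: inverse distance restricted to the 10 nearest
    neighbors, row-standardized.  ``weight_spec`` keys: ``k``,
    ``cutoff``, ``row_standardize``, or a precomputed ``matrix``.
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(z, z[0]):
        raise ValueError("Moran's I undefined for constant residuals")
    spec = dict(weight_spec or {})
    if "matrix" in spec:
        w = np.asarray(spec["matrix"], dtype=float)
    else:
        coords = np.asarray(coordinates, dtype=float)
        w = _moran_weights(coords, k=spec.get("k", 10), cutoff=spec.get("cutoff"))
    if spec.get("row_standardize", True):
        rs = w.sum(axis=1, keepdims=True)
        if (rs == 0).any():
            raise ValueError("a site has all-zero weights")
        w = w / rs
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("all-zero weight matrix")
    zc = z - z.mean()
    i_stat = (n / s0) * float(zc @ w @ zc) / float(zc @ zc)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
    zscore = (i_stat - e_i) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(
        i=float(i_stat), expected=e_i, variance=float(var),
        z=float(zscore), p=float(min(max(p, np.finfo(float).tiny), 1.0)), n=n,
    )


def check_collinearity(pop_density, impervious_pct, vif_threshold: float = 5.0):
    """Pearson r and VIF = 1/(1-r^2) between the two urbanization metrics."""
    x = np.asarray(pop_density, dtype=float)
    y = np.asarray(impervious_pct, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        warnings.warn("perfect collinearity: VIF is infinite", stacklevel=2)
        return r, float("inf")
    vif = 1.0 / (1.0 - r * r)
    if vif > vif_threshold:
        warnings.warn(f"VIF = {vif:.2f} exceeds {vif_threshold}", stacklevel=2)
    return r, float(vif)
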