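"""Laplace-approximated Bernoulli GLMM on a complete sites x species cross.

The occurrence design is a full cross of S sites and K species, which
makes every Gaussian-elimination block of the penalized-IRLS normal
equations expressible with dense reshapes instead of generic sparse
algebra: site/species cross-blocks are the (S, K) weight matrix itself.
Random intercepts: site, sampling category (sites nested in categories),
and species (crossed).  Variance components are maximized by a
Laplace-EM iteration (posterior-mode plus curvature update); the
marginal log-likelihood is the Laplace approximation at the joint mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

_CLIP_VAR = 1e-8
_BOUNDARY_COEF = 15.0


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GlmmFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    variances: dict[str, float]
    ranef: dict[str, np.ndarray]
    warnings: list[str] = field(default_factory=list)
    cov_beta: np.ndarray | None = None


class CrossedLogisticGLMM:
    """Bernoulli-logit mixed model on an (S sites) x (K species) cross.

    Parameters
    ----------
    y : (S, K) binary array of occurrences.
    x : (S*K, p) fixed-effect design, rows in site-major order
        (site index varies slowest, species fastest).
    cat_of_site : (S,) integer category code per site.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, cat_of_site: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.S, self.K = self.y.shape
        self.N = self.S * self.K
        self.x = np.asarray(x, dtype=float)
        if self.x.shape[0] != self.N:
            raise ValueError("design row count must equal S*K")
        self.p = self.x.shape[1]
        self.cat = np.asarray(cat_of_site, dtype=int)
        self.C = int(self.cat.max()) + 1 if len(self.cat) else 0
        self.q = self.S + self.C + self.K
        # category aggregation matrix applied to per-site vectors
        self._cat_onehot = np.zeros((self.C, self.S))
        self._cat_onehot[self.cat, np.arange(self.S)] = 1.0

    # -- linear predictor ---------------------------------------------------

    def _eta(self, beta, b_site, b_cat, b_sp):
        eta = (self.x @ beta).reshape(self.S, self.K)
        return eta + (b_site + b_cat[self.cat])[:, None] + b_sp[None, :]

    def _penalized_ll(self, eta, coef_re, dinv_re):
        ll = self.y * eta - np.logaddexp(0.0, eta)
        return float(ll.sum() - 0.5 * (dinv_re * coef_re * coef_re).sum())

    # -- normal-equation assembly ------------------------------------------

    def _assemble(self, w, xw_sums=None):
        """Dense (p+S+C+K)^2 penalized-IRLS normal matrix from (S,K) weights."""
        S, K, C, p = self.S, self.K, self.C, self.p
        dim = p + self.q
        a = np.zeros((dim, dim))
        wflat = w.ravel()
        xw = self.x * wflat[:, None]
        a[:p, :p] = xw.T @ self.x
        x_site = xw.reshape(S, K, p).sum(axis=1)  # (S, p)
        x_sp = xw.reshape(S, K, p).sum(axis=0)  # (K, p)
        x_cat = self._cat_onehot @ x_site  # (C, p)
        w_site = w.sum(axis=1)
        w_sp = w.sum(axis=0)
        w_cat = self._cat_onehot @ w_site
        i0, i1, i2 = p, p + S, p + S + C
        a[:p, i0:i1] = x_site.T
        a[:p, i1:i2] = x_cat.T
        a[:p, i2:] = x_sp.T
        a[i0:i1, i0:i1] = np.diag(w_site)
        a[i1:i2, i1:i2] = np.diag(w_cat)
        a[i2:, i2:] = np.diag(w_sp)
        a[i0:i1, i1:i2] = (self._cat_onehot * w_site).T  # site x cat
        a[i0:i1, i2:] = w  # site x species: the weight matrix itself
        a[i1:i2, i2:] = self._cat_onehot @ w  # cat x species
        # blocks were written in the upper triangle only; mirror them
        a = np.triu(a) + np.triu(a, 1).T
        return a

    def _score(self, resid):
        """Gradient of the unpenalized log-likelihood, same ordering."""
        rflat = resid.ravel()
        g_x = self.x.T @ rflat
        g_site = resid.sum(axis=1)
        g_cat = self._cat_onehot @ g_site
        g_sp = resid.sum(axis=0)
        return np.concatenate([g_x, g_site, g_cat, g_sp])

    def _dinv_vector(self, variances):
        v = np.concatenate(
            [
                np.full(self.S, 1.0 / max(variances["site"], _CLIP_VAR)),
                np.full(self.C, 1.0 / max(variances["category"], _CLIP_VAR)),
                np.full(self.K, 1.0 / max(variances["species"], _CLIP_VAR)),
            ]
        )
        return v

    # -- inner PIRLS --------------------------------------------------------

    def _inner(self, coef, dinv_re, tol=1e-8, max_iter=60):
        p = self.p
        beta = coef[:p]
        b_site = coef[p : p + self.S]
        b_cat = coef[p + self.S : p + self.S + self.C]
        b_sp = coef[p + self.S + self.C :]
        eta = self._eta(beta, b_site, b_cat, b_sp)
        obj = self._penalized_ll(eta, coef[p:], dinv_re)
        chol = None
        converged = False
        for _ in range(max_iter):
            mu = _sigmoid(eta)
            w = np.maximum(mu * (1.0 - mu), 1e-10)
            score = self._score(self.y - mu)
            score[p:] -= dinv_re * coef[p:]
            a = self._assemble(w)
            idx = np.arange(p, p + self.q)
            a[idx, idx] += dinv_re
            a[np.arange(p), np.arange(p)] += 1e-10
            chol = cho_factor(a, lower=True)
            step = cho_solve(chol, score)
            t = 1.0
            for _ in range(30):
                cand = coef + t * step
                eta_c = self._eta(
                    cand[:p],
                    cand[p : p + self.S],
                    cand[p + self.S : p + self.S + self.C],
                    cand[p + self.S + self.C :],
                )
                obj_c = self._penalized_ll(eta_c, cand[p:], dinv_re)
                if np.isfinite(obj_c) and obj_c >= obj - 1e-10:
                    break
                t *= 0.5
            else:
                break
            gain = obj_c - obj
            coef, eta, obj = cand, eta_c, obj_c
            if gain < tol:
                converged = True
                break
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        return coef, eta, w, obj, chol, converged

    def _laplace_ll(self, eta, coef_re, dinv_re, w, variances):
        ll = float((self.y * eta - np.logaddexp(0.0, eta)).sum())
        pen = 0.5 * float((dinv_re * coef_re * coef_re).sum())
        a = self._assemble(w)
        h_bb = a[self.p :, self.p :].copy()
        idx = np.arange(self.q)
        h_bb[idx, idx] += dinv_re
        sign, logdet_h = np.linalg.slogdet(h_bb)
        if sign <= 0:
            return -np.inf
        logdet_d = -float(np.log(dinv_re).sum())
        return ll - pen - 0.5 * (logdet_h + logdet_d)

    # -- outer EM on variance components ------------------------------------

    def fit(
        self,
        variances0: dict[str, float] | None = None,
        fix_variances: dict[str, float] | None = None,
        tol: float = 1e-6,
        max_em: int = 120,
    ) -> GlmmFit:
        """Estimate fixed effects and variance components.

        ``fix_variances`` pins named components (a value of 0 removes
        the effect); remaining components are updated by Laplace-EM
        until the relative change in every log-variance is below
        ``tol**0.5`` or the Laplace log-likelihood stabilizes.
        """
        warns: list[str] = []
        variances = {"site": 0.5, "category": 0.5, "species": 0.5}
        if variances0:
            variances.update(variances0)
        fixed = dict(fix_variances or {})
        variances.update(fixed)
        free = [k for k in variances if k not in fixed]

        coef = np.zeros(self.p + self.q)
        ybar = min(max(self.y.mean(), 1e-4), 1 - 1e-4)
        coef[0] = np.log(ybar / (1 - ybar))

        sizes = {"site": self.S, "category": self.C, "species": self.K}
        slices = {
            "site": slice(0, self.S),
            "category": slice(self.S, self.S + self.C),
            "species": slice(self.S + self.C, self.q),
        }
        ll_prev = -np.inf
        converged = False
        inner_ok = False
        eta = w = chol = None
        for it in range(max_em):
            dinv_re = self._dinv_vector(variances)
            coef, eta, w, _, chol, inner_ok = self._inner(coef, dinv_re)
            ll = self._laplace_ll(eta, coef[self.p :], dinv_re, w, variances)
            if not free:
                converged = inner_ok
                break
            # posterior curvature: diagonal of the inverse penalized Hessian
            inv_diag = np.diag(cho_solve(chol, np.eye(self.p + self.q)))[self.p :]
            moved = 0.0
            for name in free:
                sl = slices[name]
                b = coef[self.p :][sl]
                new = float((b @ b + inv_diag[sl].sum()) / sizes[name])
                new = max(new, _CLIP_VAR)
                moved = max(moved, abs(np.log(new) - np.log(max(variances[name], _CLIP_VAR))))
                variances[name] = new
            if it > 0 and (moved < 5e-3 or abs(ll - ll_prev) < 1e-4):
                converged = inner_ok
                break
            ll_prev = ll
        dinv_re = self._dinv_vector(variances)
        coef, eta, w, _, chol, inner_ok = self._inner(coef, dinv_re)
        ll = self._laplace_ll(eta, coef[self.p :], dinv_re, w, variances)
        converged = converged and inner_ok

        cov = cho_solve(chol, np.eye(self.p + self.q))
        se = np.sqrt(np.maximum(np.diag(cov)[: self.p], 0.0))
        beta = coef[: self.p]
        if np.abs(beta).max() > _BOUNDARY_COEF:
            warns.append("possible separation: a coefficient is at the boundary")
        for name in free:
            if variances[name] <= _CLIP_VAR * 10:
                warns.append(f"variance component '{name}' collapsed toward 0")
        ranef = {
            name: coef[self.p :][slices[name]].copy() for name in ("site", "category", "species")
        }
        return GlmmFit(
            beta=beta,
            se=se,
            loglik=float(ll),
            converged=bool(converged),
            variances={k: float(v) for k, v in variances.items()},
            ranef=ranef,
            warnings=warns,
            cov_beta=cov[: self.p, : self.p],
        )
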