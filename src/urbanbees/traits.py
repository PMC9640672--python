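"""Global-pool occurrence expansion and the trait x urbanization GLMM.

Every non-parasitic species in the pool is given a presence/absence
record at every site; occurrence is modeled with a binomial GLMM whose
fixed part crosses one urbanization metric with the four functional
traits (treatment coding, references: below-ground nesting, generalist
diet, social, small), plus biogeographical region, and whose random part
has site intercepts nested in sampling category plus crossed species
intercepts.  Trait-related Wald p-values are adjusted by the
Benjamini-Hochberg false-discovery-rate step-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glmm import CrossedLogisticGLMM
from .core.filters import HONEYBEE
from .core.io import normalize_species
from .core.types import (
    TRAIT_CONTRASTS,
    TRAIT_REFERENCES,
    TRAITS,
    CommunityTable,
    FitResult,
    LRTRecord,
)
from .preprocess import log_density

logger = logging.getLogger(__name__)

METRICS = ("pop_density", "impervious_pct")


@dataclass
class TraitFitResult(FitResult):
    """GLMM fit with the reference-modality map and FDR-adjusted column."""

    reference_modalities: dict[str, str] = field(
        default_factory=lambda: dict(TRAIT_REFERENCES)
    )


def expand_occurrence(
    table: CommunityTable,
    traits: pd.DataFrame,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Cross the species pool with all sites into a long occurrence table.

    The pool is the community table's species list minus the honeybee
    and any species flagged parasitic in ``traits`` (such exclusions are
    logged).  Species without a trait row keep all modalities at
    ``no_information``.  Rows are ordered site-major (sites sorted, then
    species sorted), giving ``len(pool) * n_sites`` rows.
    """
    tr = traits.set_index(traits["species"].map(normalize_species))
    pool = []
    for sp in table.species:
        key = normalize_species(sp)
        if key == normalize_species(HONEYBEE):
            logger.info("expand_occurrence: excluded %s from the pool", sp)
            continue
        if key in tr.index and bool(tr.loc[key, "parasitic"]):
            logger.info("expand_occurrence: excluded parasitic species %s", sp)
            continue
        pool.append(sp)
    if not pool:
        raise ValueError("empty species pool after filtering")
    pool = sorted(pool)

    site_meta = sites.set_index(sites["site_id"].astype(str))
    missing = [s for s in table.site_ids if s not in site_meta.index]
    if missing:
        raise ValueError(f"sites missing metadata: {missing[:10]}")
    site_order = sorted(table.site_ids)

    inc = pd.DataFrame(table.incidence, index=list(table.site_ids), columns=list(table.species))
    occ = inc.loc[site_order, pool].to_numpy().ravel()

    n_s, n_k = len(site_order), len(pool)
    out = pd.DataFrame(
        {
            "site_id": np.repeat(site_order, n_k),
            "species": np.tile(pool, n_s),
            "occurrence": occ.astype(np.int8),
        }
    )
    for col in ("pop_density", "impervious_pct", "region", "sampling_category"):
        out[col] = np.repeat(site_meta.loc[site_order, col].to_numpy(), n_k)
    trait_cols = {t: [] for t in TRAITS}
    for sp in pool:
        key = normalize_species(sp)
        for t in TRAITS:
            val = tr.loc[key, t] if key in tr.index else "no_information"
            trait_cols[t].append(val)
    for t in TRAITS:
        out[t] = np.tile(np.asarray(trait_cols[t], dtype=object), n_s)
    return out


def _trait_design(
    occ: pd.DataFrame, metric: str
) -> tuple[np.ndarray, list[str], np.ndarray, dict]:
    """Fixed-effect design in site-major row order (as built by
    :func:`expand_occurrence`)."""
    if metric == "pop_density":
        raw = log_density(occ["pop_density"].to_numpy(dtype=float))
    else:
        raw = occ["impervious_pct"].to_numpy(dtype=float)
    # standardize over sites (each site contributes pool-size identical rows)
    site_vals = pd.Series(raw).groupby(occ["site_id"].to_numpy()).first()
    m, sd = float(site_vals.mean()), float(site_vals.std(ddof=0)) or 1.0
    x_metric = (raw - m) / sd

    cols = [np.ones(len(occ)), x_metric]
    names = ["(Intercept)", metric]
    for t in TRAITS:
        for modality in (TRAIT_CONTRASTS[t], "no_information"):
            cols.append((occ[t] == modality).to_numpy(dtype=float))
            names.append(f"{t}[{modality}]")
    for t in TRAITS:
        for modality in (TRAIT_CONTRASTS[t], "no_information"):
            cols.append(x_metric * (occ[t] == modality).to_numpy(dtype=float))
            names.append(f"{metric}:{t}[{modality}]")
    region_levels = sorted(occ["region"].unique())
    for lev in region_levels[1:]:
        cols.append((occ["region"] == lev).to_numpy(dtype=float))
        names.append(f"region[{lev}]")
    scaling = {"metric": metric, "mean": m, "sd": sd}
    return np.column_stack(cols), names, x_metric, scaling


def _bh_family(names: list[str], metric: str) -> list[int]:
    """Indices of the 8 informative trait tests (main + interaction)."""
    fam = []
    for t in TRAITS:
        fam.append(names.index(f"{t}[{TRAIT_CONTRASTS[t]}]"))
    for t in TRAITS:
        fam.append(names.index(f"{metric}:{t}[{TRAIT_CONTRASTS[t]}]"))
    return fam


def fit_trait_glmm(
    occurrence_table: pd.DataFrame,
    metric: str,
    seed: int = 0,
    region_lrt: bool = True,
    bh_include_metric: bool = False,
) -> TraitFitResult:
    """Fit the binomial trait-filtering GLMM for one urbanization metric.

    ``metric`` selects ``pop_density`` (entered as z-scored ``log(x+1)``)
    or ``impervious_pct`` (z-scored).  Random intercepts: site nested in
    sampling category, plus crossed species.  The BH family defaults to
    the eight informative trait tests (four main effects, four
    interactions); set ``bh_include_metric`` to add the metric main
    effect.  ``region_lrt`` refits without region for the region LRT.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    occ = occurrence_table.sort_values(["site_id", "species"], kind="mergesort").reset_index(
        drop=True
    )
    site_ids = occ["site_id"].unique()
    species = occ["species"].unique()
    n_s, n_k = len(site_ids), len(species)
    if len(occ) != n_s * n_k:
        raise ValueError("occurrence table is not a complete sites x species cross")

    x_mat, names, _, scaling = _trait_design(occ, metric)
    y = occ["occurrence"].to_numpy(dtype=float).reshape(n_s, n_k)
    cat_labels = occ.groupby("site_id", sort=True)["sampling_category"].first()
    for fct in ("sampling_category",):
        if cat_labels.nunique() < 2:
            raise ValueError("need >= 2 levels for every random grouping factor")
    cat_codes = pd.Categorical(cat_labels).codes

    model = CrossedLogisticGLMM(y, x_mat, cat_codes)
    fit = model.fit()

    zval = np.divide(fit.beta, fit.se, out=np.full_like(fit.beta, np.nan), where=fit.se > 0)
    pval = 2 * stats.norm.sf(np.abs(zval))
    family = _bh_family(names, metric)
    if bh_include_metric:
        family = [names.index(metric)] + family
    p_adj = np.full(len(names), np.nan)
    p_adj[family] = fdr_adjust(pval[family])

    table = pd.DataFrame(
        {"term": names, "estimate": fit.beta, "se": fit.se, "z": zval, "p": pval, "p_adj": p_adj}
    )
    result = TraitFitResult(
        label=f"traits_{metric}",
        coef=table,
        loglik=fit.loglik,
        converged=fit.converged,
        variance_components=fit.variances,
        n_obs=n_s * n_k,
        warnings=list(fit.warnings),
        metadata={"scaling": scaling, "seed": seed, "n_sites": n_s, "n_species": n_k,
                  "cov_beta": fit.cov_beta},
    )
    if not fit.converged:
        logger.warning("fit_trait_glmm(%s): non-convergence flagged", metric)

    if region_lrt and any(nm.startswith("region[") for nm in names):
        keep = [i for i, nm in enumerate(names) if not nm.startswith("region[")]
        reduced_fit = CrossedLogisticGLMM(y, x_mat[:, keep], cat_codes).fit()
        chi2 = max(2.0 * (fit.loglik - reduced_fit.loglik), 0.0)
        df = len(names) - len(keep)
        result.lrt.append(
            LRTRecord(term="region", chi2=float(chi2), df=df, p=float(stats.chi2.sf(chi2, df)))
        )
    return result


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def trait_occurrence_curves(
    fit: TraitFitResult,
    metric_grid,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Predicted occurrence probabilities along the metric gradient.

    One curve per trait with the single named modality switched from the
    all-reference profile, plus the reference curve itself; random
    effects at 0 and delta-method confidence bands on the logit scale.
    ``metric_grid`` is on the standardized metric scale used by the fit.
    """
    if not fit.converged:
        raise ValueError("predictions require a converged fit")
    metric = fit.metadata["scaling"]["metric"]
    names = list(fit.coef["term"])
    beta = fit.coef["estimate"].to_numpy(dtype=float)
    cov = fit.metadata.get("cov_beta")
    if cov is None:
        cov = np.diag(fit.coef["se"].to_numpy(dtype=float) ** 2)
    cov = np.asarray(cov, dtype=float)
    grid = np.asarray(metric_grid, dtype=float)
    zq = stats.norm.ppf(0.5 + ci_level / 2)

    curves = []
    profiles = [("reference", None)] + [(t, TRAIT_CONTRASTS[t]) for t in TRAITS]
    for label, switch in profiles:
        for g in grid:
            row = np.zeros(len(names))
            row[names.index("(Intercept)")] = 1.0
            row[names.index(metric)] = g
            if switch is not None:
                row[names.index(f"{label}[{switch}]")] = 1.0
                row[names.index(f"{metric}:{label}[{switch}]")] = g
            lin = float(row @ beta)
            var = float(row @ cov @ row)
            sd = np.sqrt(max(var, 0.0))
            curves.append(
                {
                    "curve": label if switch is None else f"{label}={switch}",
                    "metric_value": g,
                    "probability": float(1 / (1 + np.exp(-lin))),
                    "lower": float(1 / (1 + np.exp(-(lin - zq * sd)))),
                    "upper": float(1 / (1 + np.exp(-(lin + zq * sd)))),
                }
            )
    return pd.DataFrame(curves)
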