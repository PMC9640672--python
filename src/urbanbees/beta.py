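"""Gradient-binned mean pairwise beta-diversity and its trend test.

Sites are binned into fixed-width intervals along an urbanization axis
(optionally ``log(x+1)``-transformed); the mean within-interval pairwise
Sorensen dissimilarity is regressed on interval midpoints by OLS to test
the homogenization hypothesis (ever-decreasing dissimilarity with
urbanization).  Intervals retaining fewer than two sites are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core.types import BetaLevelSummary, BetaMatrix
from .preprocess import log_density

logger = logging.getLogger(__name__)


def bin_gradient(
    values,
    width: float,
    transform: str = "identity",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign each value to a half-open interval ``[k*w, (k+1)*w)``.

    Intervals are anchored at 0; the global maximum is assigned to the
    last interval (closed on the right), so the number of intervals is
    ``ceil(max / width)`` (1 when all values are 0).  Returns the level
    index per value and a frame of interval bounds including empty
    levels inside the range (``n_sites = 0``).
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if transform not in ("identity", "log1p"):
        raise ValueError(f"unknown transform {transform!r}")
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("gradient values must be >= 0")
    if transform == "log1p":
        x = log_density(x)
    vmax = float(x.max()) if x.size else 0.0
    n_levels = max(int(np.ceil(vmax / width)), 1)
    levels = np.minimum(np.floor(x / width).astype(int), n_levels - 1)
    counts = np.bincount(levels, minlength=n_levels)
    bounds = pd.DataFrame(
        {
            "level": np.arange(n_levels),
            "lower": np.arange(n_levels) * width,
            "upper": (np.arange(n_levels) + 1) * width,
            "n_sites": counts,
        }
    )
    return levels, bounds


def summarize_levels(
    levels: np.ndarray,
    bounds: pd.DataFrame,
    beta_matrix: BetaMatrix,
    coordinates: np.ndarray,
    min_sites: int = 2,
) -> list[BetaLevelSummary]:
    """Mean within-level pairwise dissimilarity and geographic distance.

    Levels with fewer than ``min_sites`` sites are excluded (and
    logged).  ``coordinates`` is an (n, 2) array of planar meters
    aligned with the beta matrix's site order.
    """
    levels = np.asarray(levels)
    if len(levels) != len(beta_matrix.site_ids):
        raise ValueError("level assignments do not match the beta matrix")
    xy = np.asarray(coordinates, dtype=float)
    out: list[BetaLevelSummary] = []
    for _, row in bounds.iterrows():
        idx = np.flatnonzero(levels == row["level"])
        if len(idx) < min_sites:
            if len(idx) > 0:
                logger.info("level %d excluded (%d site(s))", int(row["level"]), len(idx))
            continue
        sub = beta_matrix.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        d = xy[idx]
        dist = np.sqrt(((d[:, None, :] - d[None, :, :]) ** 2).sum(-1))
        out.append(
            BetaLevelSummary(
                level=int(row["level"]),
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                n_sites=len(idx),
                mean_dissimilarity=float(sub[iu].mean()),
                mean_distance_m=float(dist[iu].mean()),
            )
        )
    if not out:
        raise ValueError(f"no level retains >= {min_sites} sites")
    return out


@dataclass
class TrendReport:
    """OLS trend of mean within-level dissimilarity on interval midpoint."""

    slope: float
    slope_se: float
    intercept: float
    t: float
    p: float
    n_levels: int
    shapiro_p: float
    confounders: dict[str, dict[str, float]] = field(default_factory=dict)
    weighted: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "t": self.t,
            "p": self.p,
            "n_levels": self.n_levels,
            "shapiro_p": self.shapiro_p,
            "confounders": self.confounders,
            "weighted": self.weighted,
            "warnings": self.warnings,
        }


def homogenization_trend(
    level_summaries: list[BetaLevelSummary],
    weighted: bool = False,
) -> TrendReport:
    """Regress level mean dissimilarities on interval midpoints.

    Unweighted OLS with Gaussian errors by default; ``weighted=True``
    weights levels by their within-level pair count.  Residual normality
    (Shapiro-Wilk) and the two confounder correlations (level midpoint
    vs. site count and vs. mean geographic distance, Pearson tests) are
    reported as diagnostics only.
    """
    if len(level_summaries) < 3:
        raise ValueError("need at least 3 retained levels for a trend test")
    mid = np.array([s.midpoint for s in level_summaries])
    y = np.array([s.mean_dissimilarity for s in level_summaries])
    n_sites = np.array([s.n_sites for s in level_summaries])
    geo = np.array([s.mean_distance_m for s in level_summaries])
    warns: list[str] = []

    x = sm.add_constant(mid)
    if weighted:
        w = n_sites * (n_sites - 1) / 2.0
        model = sm.WLS(y, x, weights=w).fit()
    else:
        model = sm.OLS(y, x).fit()
    if np.allclose(y, y[0]):
        warns.append("degenerate fit: zero-variance response")
        slope, se, tval, p = 0.0, float("nan"), float("nan"), float("nan")
        shapiro_p = float("nan")
    else:
        slope = float(model.params[1])
        se = float(model.bse[1])
        tval = float(model.tvalues[1])
        p = float(model.pvalues[1])
        resid = model.resid
        if len(resid) >= 3 and not np.allclose(resid, resid[0]):
            shapiro_p = float(stats.shapiro(resid).pvalue)
        else:
            shapiro_p = float("nan")

    confounders = {}
    for name, v in (("n_sites", n_sites), ("mean_distance_m", geo)):
        if np.std(v) == 0:
            confounders[name] = {"r": float("nan"), "p": float("nan")}
        else:
            r, pr = stats.pearsonr(mid, v)
            confounders[name] = {"r": float(r), "p": float(pr)}

    return TrendReport(
        slope=slope,
        slope_se=se,
        intercept=float(model.params[0]),
        t=tval,
        p=p,
        n_levels=len(level_summaries),
        shapiro_p=shapiro_p,
        confounders=confounders,
        weighted=weighted,
        warnings=warns,
    )
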