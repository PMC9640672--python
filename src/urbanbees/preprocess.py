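"""Spatial aggregation of nearby sites and sampling-scheme categorization.

Neighboring sampling locations are merged by complete-linkage
hierarchical clustering on planar Euclidean distance, cut at a distance
threshold (default 500 m), so that the maximum pairwise distance within
any group never exceeds the cutoff.  Sampling-effort metadata are then
consensus-clustered (k-means x hierarchical cross-tabulation) into broad
sampling-scheme categories used downstream as a random grouping factor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

EFFORT_VARIABLES = ["active_days", "passive_hours", "kick_net"]


def log_density(pop_density):
    """Natural-log ``log(x + 1)`` transform for population density."""
    x = np.asarray(pop_density, dtype=float)
    if (x < 0).any():
        raise ValueError("pop_density must be >= 0")
    out = np.log1p(x)
    return float(out) if np.isscalar(pop_density) or out.ndim == 0 else out


def aggregate_sites(
    sites: pd.DataFrame,
    records: pd.DataFrame | None = None,
    cutoff_m: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Merge sites closer than ``cutoff_m`` into grouped pseudo-sites.

    Complete linkage guarantees the maximum pairwise distance within a
    group is at most the cutoff.  Group attributes: barycenter
    coordinates and mean urbanization metrics (unweighted means), summed
    ``active_days`` and ``passive_hours``, max ``kick_net``, majority
    region (ties broken by first member in input order).  Records are
    re-keyed to group ids; the member list is returned in the
    ``members`` column.
    """
    if sites.empty:
        raise ValueError("no sites to aggregate")
    if cutoff_m <= 0:
        raise ValueError("cutoff_m must be > 0")
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    if len(sites) == 1:
        labels = np.array([1])
    else:
        tree = linkage(pdist(xy), method="complete")
        labels = fcluster(tree, t=cutoff_m, criterion="distance")

    sites = sites.reset_index(drop=True)
    groups = []
    mapping: dict[str, str] = {}
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members = sites.loc[idx, "site_id"].astype(str).tolist()
        gid = f"G{min(idx):04d}" if len(members) > 1 else members[0]
        def _majority(col):
            counts = sites.loc[idx, col].value_counts()
            winners = set(counts[counts == counts.max()].index)
            # ties -> first member's value in input order
            return next(v for v in sites.loc[idx, col] if v in winners)

        region = _majority("region")
        groups.append(
            {
                "site_id": gid,
                "x": float(sites.loc[idx, "x"].mean()),
                "y": float(sites.loc[idx, "y"].mean()),
                "pop_density": float(sites.loc[idx, "pop_density"].mean()),
                "impervious_pct": float(sites.loc[idx, "impervious_pct"].mean()),
                "region": region,
                "active_days": float(sites.loc[idx, "active_days"].sum()),
                "passive_hours": float(sites.loc[idx, "passive_hours"].sum()),
                "kick_net": int(sites.loc[idx, "kick_net"].max()),
                "n_members": len(members),
                "members": ";".join(members),
                # carry a pre-existing sampling category by majority vote;
                # left missing otherwise for assign_sampling_categories
                "sampling_category": (
                    _majority("sampling_category")
                    if "sampling_category" in sites.columns
                    and sites.loc[idx, "sampling_category"].notna().all()
                    else pd.NA
                ),
            }
        )
        for m in members:
            mapping[m] = gid
    grouped = pd.DataFrame(groups).sort_values("site_id").reset_index(drop=True)

    remapped = None
    if records is not None:
        remapped = records.copy()
        remapped["site_id"] = remapped["site_id"].astype(str).map(mapping)
        if remapped["site_id"].isna().any():
            raise ValueError("records reference sites absent from the site table")
    logger.info("aggregate_sites: %d sites -> %d groups", len(sites), len(grouped))
    return grouped, remapped


def _consensus_categories(
    km_labels: np.ndarray,
    hc_labels: np.ndarray,
    z: np.ndarray,
    min_category_size: int,
) -> np.ndarray:
    """Cross-tabulate two labelings; merge small cells into the nearest
    (standardized effort centroid) surviving cell."""
    pairs = pd.Series(list(zip(km_labels, hc_labels)))
    codes, uniques = pd.factorize(pairs, sort=True)
    counts = np.bincount(codes)
    keep = np.flatnonzero(counts >= min_category_size)
    if len(keep) == 0:  # everything small: keep the largest cell only
        keep = np.array([int(np.argmax(counts))])
    centroids = np.vstack([z[codes == k].mean(axis=0) for k in keep])
    out = codes.copy()
    for k in range(len(uniques)):
        if k in keep:
            out[codes == k] = int(np.flatnonzero(keep == k)[0])
        else:
            cell_centroid = z[codes == k].mean(axis=0)
            nearest = int(np.argmin(((centroids - cell_centroid) ** 2).sum(axis=1)))
            out[codes == k] = nearest
    # re-factorize to consecutive labels
    return pd.factorize(out, sort=True)[0]


def _silhouette_k(z: np.ndarray, labeler, k_range=range(2, 9)) -> int:
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(z):
            break
        labels = labeler(z, k)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(z, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("could not select k by silhouette")
    return best_k


def assign_sampling_categories(
    grouped_sites: pd.DataFrame,
    k_kmeans: int | None = 3,
    k_hier: int | None = 4,
    min_category_size: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each site a sampling-scheme category label.

    The three effort variables are z-scored (zero-variance variables are
    dropped with a warning), labeled independently by k-means (25
    restarts, fixed seed) and complete-linkage hierarchical clustering,
    and the two partitions combined by cross-tabulation.  Non-empty
    cross-table cells become candidate categories; cells smaller than
    ``min_category_size`` are merged into the nearest surviving
    candidate.  Passing ``None`` for either k selects it in 2..8 by
    maximum mean silhouette width.

    Returns a copy of ``grouped_sites`` with a ``sampling_category``
    column (labels ``C0``, ``C1``, ...).
    """
    if len(grouped_sites) < 2:
        raise ValueError("need at least 2 sites to categorize")
    eff = grouped_sites[EFFORT_VARIABLES].to_numpy(dtype=float)
    sd = eff.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        out = grouped_sites.copy()
        out["sampling_category"] = "C0"
        return out
    if not keep.all():
        dropped = [v for v, k in zip(EFFORT_VARIABLES, keep) if not k]
        logger.warning("zero-variance effort variable(s) dropped: %s", dropped)
    z = (eff[:, keep] - eff[:, keep].mean(axis=0)) / sd[keep]

    def km_labeler(data, k):
        return KMeans(n_clusters=k, n_init=25, random_state=seed).fit_predict(data)

    def hc_labeler(data, k):
        return fcluster(linkage(pdist(data), method="complete"), t=k, criterion="maxclust")

    # degenerate: all effort profiles identical after standardization
    if np.allclose(z, z[0]):
        out = grouped_sites.copy()
        out["sampling_category"] = "C0"
        return out

    if k_kmeans is None:
        k_kmeans = _silhouette_k(z, km_labeler)
    if k_hier is None:
        k_hier = _silhouette_k(z, hc_labeler)
    if k_kmeans > len(z) or k_hier > len(z):
        raise ValueError("fewer sites than requested number of clusters")

    km = km_labeler(z, k_kmeans)
    hc = hc_labeler(z, k_hier)
    cats = _consensus_categories(np.asarray(km), np.asarray(hc), z, min_category_size)
    out = grouped_sites.copy()
    out["sampling_category"] = [f"C{c}" for c in cats]
    logger.info(
        "assign_sampling_categories: %d categories from %dx%d cross-tab",
        out["sampling_category"].nunique(), k_kmeans, k_hier,
    )
    return out
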