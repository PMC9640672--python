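"""Richness, sample-coverage, and pairwise Sorensen dissimilarity.

Sorensen dissimilarity on presence/absence data is
``(b + c) / (2a + b + c)`` where ``a`` counts shared species and ``b``,
``c`` the species unique to either community.  Sample coverage uses the
abundance-based closed forms: ``C_hat = 1 - (f1/n) * (n-1)f1 /
((n-1)f1 + 2 f2)`` with the Chao1 asymptotic richness estimate as the
expected-richness denominator.
"""

from __future__ import annotations

from collections.abc import Iterable, Set

import numpy as np

from .core.types import BetaMatrix, CommunityTable, CoverageEstimate


def richness(incidence_row: Iterable[int]) -> int:
    """Number of species present (count of non-zero incidence cells)."""
    row = np.asarray(list(incidence_row) if not isinstance(incidence_row, np.ndarray) else incidence_row)
    return int((row != 0).sum())


def sorensen(species_a: Set[str], species_b: Set[str]) -> float:
    """Sorensen dissimilarity between two non-empty species sets."""
    a_set, b_set = set(species_a), set(species_b)
    if not a_set or not b_set:
        raise ValueError("sorensen is undefined for an empty community")
    a = len(a_set & b_set)
    b = len(a_set - b_set)
    c = len(b_set - a_set)
    return (b + c) / (2 * a + b + c)


def pairwise_beta(table: CommunityTable) -> BetaMatrix:
    """All unordered pairwise Sorensen dissimilarities between sites."""
    if table.n_sites < 2:
        raise ValueError("need at least 2 sites for pairwise dissimilarity")
    inc = table.incidence.astype(bool)
    if (~inc.any(axis=1)).any():
        raise ValueError("empty community row")
    n = table.n_sites
    # vectorized set arithmetic on the incidence matrix
    shared = inc.astype(np.int64) @ inc.T.astype(np.int64)
    sizes = inc.sum(axis=1)
    tot = sizes[:, None] + sizes[None, :]
    # (b+c)/(2a+b+c): b+c = tot-2a and 2a+b+c = tot
    mat = (tot - 2 * shared) / tot.astype(float)
    np.fill_diagonal(mat, 0.0)
    assert mat.shape == (n, n)
    return BetaMatrix(site_ids=table.site_ids, values=mat)


def sample_coverage(abundance_vector: Iterable[int], site_id: str = "") -> CoverageEstimate:
    """Coverage and Chao1 asymptotic richness from a site's abundances.

    ``f2 = 0`` falls back to the bias-corrected Chao1 term
    ``f1 (f1 - 1) / 2``; no singletons gives complete coverage.
    """
    raw = np.asarray(list(abundance_vector), dtype=np.int64)
    if raw.size and (raw < 0).any():
        raise ValueError("abundances must be >= 0")
    ab = raw[raw > 0]
    if ab.size == 0:
        raise ValueError("empty abundance vector")
    n = int(ab.sum())
    s_obs = int(ab.size)
    f1 = int((ab == 1).sum())
    f2 = int((ab == 2).sum())
    if f1 == 0:
        c_hat = 1.0
    else:
        denom = (n - 1) * f1 + 2 * f2
        # n = 1 makes the bracket 0/0; its f2 = 0 limit is 1, giving C = 0
        bracket = (n - 1) * f1 / denom if denom > 0 else 1.0
        c_hat = 1.0 - (f1 / n) * bracket
    if f2 > 0:
        s_est = s_obs + f1 * f1 / (2 * f2)
    else:
        s_est = s_obs + f1 * (f1 - 1) / 2
    s_est = max(float(s_est), float(s_obs))
    return CoverageEstimate(
        site_id=site_id, n=n, s_obs=s_obs, f1=f1, f2=f2, c_hat=float(c_hat), s_est=s_est
    )


def coverage_table(table: CommunityTable) -> list[CoverageEstimate]:
    """Per-site coverage estimates for a community table."""
    return [
        sample_coverage(table.abundance[i], site_id=sid)
        for i, sid in enumerate(table.site_ids)
    ]
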