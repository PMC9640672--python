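"""Domain types shared across the pipeline.

Tabular collections (survey sites, specimen records, trait profiles) are
carried as validated :class:`pandas.DataFrame` objects with documented
schemas (see :mod:`urbanbees.core.io`); the richer composite results are
dataclasses defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("Continental", "Atlantic", "Mediterranean", "Alpine")

NESTING_LEVELS = ("above", "below", "no_information")
SOCIALITY_LEVELS = ("social", "solitary", "no_information")
DIET_LEVELS = ("generalist", "specialist", "no_information")
SIZE_LEVELS = ("small", "large", "no_information")

#: ITD threshold (mm) separating the small and large size classes.
ITD_SIZE_CUT_MM = 2.0

#: Reference modality of each trait in treatment coding.
TRAIT_REFERENCES = {
    "nesting": "below",
    "diet": "generalist",
    "sociality": "social",
    "size": "small",
}

#: Non-reference informative modality of each trait.
TRAIT_CONTRASTS = {
    "nesting": "above",
    "diet": "specialist",
    "sociality": "solitary",
    "size": "large",
}

TRAITS = ("nesting", "diet", "sociality", "size")


@dataclass(frozen=True)
class CommunityTable:
    """Sites x species abundance/incidence matrices with deterministic order.

    Row and column labels are sorted lexicographically.  The incidence
    matrix is derived (``abundance >= 1``); no all-zero site rows are
    permitted after construction.
    """

    site_ids: tuple[str, ...]
    species: tuple[str, ...]
    abundance: np.ndarray  # (n_sites, n_species) non-negative ints

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundance)
        if ab.shape != (len(self.site_ids), len(self.species)):
            raise ValueError("abundance shape does not match labels")
        if (ab < 0).any():
            raise ValueError("abundance must be non-negative")
        if ab.shape[0] and (ab.sum(axis=1) == 0).any():
            bad = [s for s, tot in zip(self.site_ids, ab.sum(axis=1)) if tot == 0]
            raise ValueError(f"null community for site(s): {bad}")
        object.__setattr__(self, "abundance", ab.astype(np.int64))

    @property
    def incidence(self) -> np.ndarray:
        return (self.abundance >= 1).astype(np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_set(self, site_id: str) -> frozenset[str]:
        i = self.site_ids.index(site_id)
        row = self.abundance[i]
        return frozenset(sp for sp, a in zip(self.species, row) if a >= 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundance, index=list(self.site_ids), columns=list(self.species)
        )


@dataclass(frozen=True)
class CoverageEstimate:
    """Abundance-based sample-coverage and asymptotic-richness summary."""

    site_id: str
    n: int
    s_obs: int
    f1: int
    f2: int
    c_hat: float
    s_est: float

    @property
    def pct_of_expected(self) -> float:
        return 100.0 * self.s_obs / self.s_est


@dataclass(frozen=True)
class BetaMatrix:
    """Symmetric pairwise Sorensen dissimilarity matrix."""

    site_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.site_ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match site count")
        if not np.allclose(v, v.T):
            raise ValueError("beta matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("beta matrix must have a zero diagonal")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("beta values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def pair(self, a: str, b: str) -> float:
        i, j = self.site_ids.index(a), self.site_ids.index(b)
        return float(self.values[i, j])

    def to_long(self) -> pd.DataFrame:
        """Long-format (site_a, site_b, dissimilarity) over unordered pairs."""
        rows = []
        for i in range(len(self.site_ids)):
            for j in range(i + 1, len(self.site_ids)):
                rows.append((self.site_ids[i], self.site_ids[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["site_a", "site_b", "dissimilarity"])


@dataclass
class LRTRecord:
    term: str
    chi2: float
    df: int
    p: float


@dataclass
class FitResult:
    """One fitted model: coefficient table, variance components, LRTs."""

    label: str
    coef: pd.DataFrame  # columns: term, estimate, se, z, p, p_adj (optional)
    loglik: float
    converged: bool
    variance_components: dict[str, float] = field(default_factory=dict)
    lrt: list[LRTRecord] = field(default_factory=list)
    n_obs: int = 0
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def coefficient(self, term: str) -> pd.Series:
        sub = self.coef[self.coef["term"] == term]
        if sub.empty:
            raise KeyError(term)
        return sub.iloc[0]

    def lrt_for(self, term: str) -> LRTRecord:
        for rec in self.lrt:
            if rec.term == term:
                return rec
        raise KeyError(term)


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its normal-approximation null moments."""

    i: float
    expected: float
    variance: float
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class BetaLevelSummary:
    """Mean pairwise dissimilarity within one urbanization interval."""

    level: int
    lower: float
    upper: float
    n_sites: int
    mean_dissimilarity: float
    mean_distance_m: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)
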