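"""Construction of the sites x species community table."""

from __future__ import annotations

import pandas as pd

from .types import CommunityTable


def build_community_table(records: pd.DataFrame, sites: pd.DataFrame) -> CommunityTable:
    """Cross-tabulate specimen records into a :class:`CommunityTable`.

    Abundance cells sum the counts of all records for a (site, species)
    pair; incidence is derived.  Rows and columns are ordered
    lexicographically.  Sites with no records are excluded (there must be
    no null community), and an entirely empty record set is an error.
    """
    if records.empty:
        raise ValueError("no records: cannot build a community table")
    known = set(sites["site_id"].astype(str))
    unknown = set(records["site_id"].astype(str)) - known
    if unknown:
        raise ValueError(f"records reference unknown site(s): {sorted(unknown)[:10]}")
    pivot = (
        records.groupby(["site_id", "species"])["count"]
        .sum()
        .unstack(fill_value=0)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return CommunityTable(
        site_ids=tuple(str(s) for s in pivot.index),
        species=tuple(pivot.columns),
        abundance=pivot.to_numpy(),
    )
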