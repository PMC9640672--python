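"""Taxon filters applied before any community-level analysis."""

from __future__ import annotations

import logging

import pandas as pd

from .io import normalize_species

logger = logging.getLogger(__name__)

HONEYBEE = "Apis mellifera"


def filter_taxa(
    records: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    drop_honeybee: bool = True,
    drop_parasitic: bool = False,
) -> pd.DataFrame:
    """Remove managed honeybee and/or parasitic-species records.

    Species without a trait row are treated as non-parasitic (a warning
    is logged), so ``drop_parasitic`` never removes unknown taxa.  The
    number of removed records is logged; the operation is idempotent and
    the two flags commute.
    """
    out = records
    if drop_honeybee:
        key = normalize_species(HONEYBEE)
        mask = out["species"].map(normalize_species) == key
        if mask.any():
            logger.info("filter_taxa: removed %d honeybee record(s)", int(mask.sum()))
        out = out[~mask]
    if drop_parasitic:
        if traits is None:
            raise ValueError("drop_parasitic requires a trait table")
        parasitic = {
            normalize_species(sp)
            for sp, flag in zip(traits["species"], traits["parasitic"])
            if bool(flag)
        }
        keys = out["species"].map(normalize_species)
        unknown = set(keys) - set(traits["species"].map(normalize_species))
        if unknown:
            logger.warning(
                "filter_taxa: %d species lack a parasitic flag; treated as non-parasitic",
                len(unknown),
            )
        mask = keys.isin(parasitic)
        if mask.any():
            logger.info("filter_taxa: removed %d parasitic record(s)", int(mask.sum()))
        out = out[~mask]
    return out.reset_index(drop=True) if out is not records else records
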