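"""Delimited-file input with schema validation, and result serialization.

File schemas (CSV by default, TSV via ``format_options={"delimiter": "\\t"}``):

``records``
    ``site_id,species,count[,year]`` — one row per (site, species, batch)
    with ``count >= 1``.
``sites``
    ``site_id,x,y,pop_density,impervious_pct,region,active_days,``
    ``passive_hours,kick_net``.  Coordinates are planar meters in a
    projected CRS (any national grid); pass
    ``format_options={"coords": "lonlat"}`` to have geographic
    coordinates converted to local equirectangular meters at load time.
``traits``
    ``species,nesting,sociality,diet,size,itd_mm,parasitic`` with the
    modality vocabularies of :mod:`urbanbees.core.types`.

Every result object can be written as a delimited table plus a JSON
sidecar (``<path>.meta.json``) holding the object kind, scalar fields and
user metadata, and read back losslessly with :func:`read_result`.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DIET_LEVELS,
    NESTING_LEVELS,
    REGIONS,
    SIZE_LEVELS,
    SOCIALITY_LEVELS,
    BetaLevelSummary,
    CoverageEstimate,
    FitResult,
    LRTRecord,
    MoranResult,
)


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class SchemaError(ValidationError):
    """A mandatory column is missing or mis-typed."""


class ReferentialError(ValidationError):
    """A record references a site that does not exist."""


class ParseError(ValidationError):
    """A cell could not be parsed as its declared type."""


RECORD_COLUMNS = ["site_id", "species", "count"]
SITE_COLUMNS = [
    "site_id",
    "x",
    "y",
    "pop_density",
    "impervious_pct",
    "region",
    "active_days",
    "passive_hours",
    "kick_net",
]
TRAIT_COLUMNS = ["species", "nesting", "sociality", "diet", "size", "itd_mm", "parasitic"]

_EARTH_RADIUS_M = 6_371_000.0


def normalize_species(name: str) -> str:
    """Case-insensitive match key after whitespace normalization."""
    return " ".join(str(name).split()).lower()


def canonical_species(name: str) -> str:
    return " ".join(str(name).split())


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def _to_float(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna()]
    if len(bad):
        raise ParseError(
            f"{what}: non-numeric value in column '{col}' at row(s) "
            f"{[int(i) + 2 for i in bad[:5]]} (1-based, incl. header)"
        )
    return out


def _lonlat_to_planar(lon: pd.Series, lat: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Local equirectangular projection around the dataset centroid."""
    lat0 = math.radians(float(lat.mean()))
    x = np.radians(lon - lon.mean()) * math.cos(lat0) * _EARTH_RADIUS_M
    y = np.radians(lat - lat.mean()) * _EARTH_RADIUS_M
    return pd.Series(x, index=lon.index), pd.Series(y, index=lat.index)


def load_sites(path: str | Path, format_options: dict | None = None) -> pd.DataFrame:
    opts = dict(format_options or {})
    df = pd.read_csv(path, sep=opts.get("delimiter", ","))
    _require_columns(df, SITE_COLUMNS, "sites")
    df = df.copy()
    df["site_id"] = df["site_id"].astype(str)
    for col in ("x", "y", "pop_density", "impervious_pct", "active_days", "passive_hours"):
        df[col] = _to_float(df, col, "sites")
    df["kick_net"] = _to_float(df, "kick_net", "sites").astype(int)

    def _row_err(mask: pd.Series, msg: str) -> None:
        if mask.any():
            rows = [int(i) + 2 for i in df.index[mask][:5]]
            raise ValidationError(f"sites: {msg} at row(s) {rows}")

    _row_err(~df["impervious_pct"].between(0, 100), "impervious_pct outside [0, 100]")
    _row_err(df["pop_density"] < 0, "pop_density < 0")
    _row_err(df["active_days"] < 0, "active_days < 0")
    _row_err(df["passive_hours"] < 0, "passive_hours < 0")
    _row_err(~df["kick_net"].isin([0, 1]), "kick_net not in {0, 1}")
    _row_err(~df["region"].isin(REGIONS), f"region not in {set(REGIONS)}")
    _row_err(df["site_id"].duplicated(), "duplicate site_id")

    if opts.get("coords") == "lonlat":
        df["x"], df["y"] = _lonlat_to_planar(df["x"], df["y"])
    if "sampling_category" not in df.columns:
        df["sampling_category"] = pd.NA
    return df.reset_index(drop=True)


def load_records(
    path: str | Path,
    sites: pd.DataFrame | None = None,
    format_options: dict | None = None,
) -> pd.DataFrame:
    opts = dict(format_options or {})
    df = pd.read_csv(path, sep=opts.get("delimiter", ","))
    _require_columns(df, RECORD_COLUMNS, "records")
    df = df.copy()
    df["site_id"] = df["site_id"].astype(str)
    df["species"] = df["species"].map(canonical_species)
    df["count"] = _to_float(df, "count", "records")
    bad = df["count"] < 1
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad][:5]]
        raise ValidationError(f"records: count < 1 at row(s) {rows}")
    df["count"] = df["count"].astype(int)
    if "year" not in df.columns:
        df["year"] = pd.NA
    if sites is not None:
        orphans = sorted(set(df["site_id"]) - set(sites["site_id"]))
        if orphans:
            raise ReferentialError(
                f"records reference unknown site_id(s): {orphans[:10]}"
            )
    return df.reset_index(drop=True)


def load_traits(path: str | Path, format_options: dict | None = None) -> pd.DataFrame:
    opts = dict(format_options or {})
    df = pd.read_csv(path, sep=opts.get("delimiter", ","))
    _require_columns(df, ["species", "nesting", "sociality", "diet", "size", "parasitic"], "traits")
    df = df.copy()
    df["species"] = df["species"].map(canonical_species)
    if "itd_mm" not in df.columns:
        df["itd_mm"] = np.nan
    df["itd_mm"] = _to_float(df, "itd_mm", "traits")
    for col, levels in (
        ("nesting", NESTING_LEVELS),
        ("sociality", SOCIALITY_LEVELS),
        ("diet", DIET_LEVELS),
        ("size", SIZE_LEVELS),
    ):
        df[col] = df[col].fillna("no_information")
        bad = ~df[col].isin(levels)
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad][:5]]
            raise ValidationError(
                f"traits: {col} not in {set(levels)} at row(s) {rows}"
            )
    df["parasitic"] = df["parasitic"].astype(bool)
    # size class must agree with ITD when both are present
    has_itd = df["itd_mm"].notna()
    small_bad = has_itd & (df["size"] == "small") & (df["itd_mm"] >= 2.0)
    large_bad = has_itd & (df["size"] == "large") & (df["itd_mm"] <= 2.0)
    if (small_bad | large_bad).any():
        rows = [int(i) + 2 for i in df.index[small_bad | large_bad][:5]]
        raise ValidationError(
            f"traits: size class inconsistent with itd_mm (cut at 2 mm) at row(s) {rows}"
        )
    dup = df["species"].map(normalize_species).duplicated()
    if dup.any():
        rows = [int(i) + 2 for i in df.index[dup][:5]]
        raise ValidationError(f"traits: duplicate species at row(s) {rows}")
    return df.reset_index(drop=True)


def load_dataset(
    records_path: str | Path,
    sites_path: str | Path,
    traits_path: str | Path,
    format_options: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate the three survey tables.

    Returns ``(records, sites, traits)``.  Species appearing in the
    records but absent from the trait table are permitted; downstream
    consumers treat their traits as ``no_information`` / non-parasitic.
    """
    sites = load_sites(sites_path, format_options)
    records = load_records(records_path, sites, format_options)
    traits = load_traits(traits_path, format_options)
    return records, sites, traits


# ---------------------------------------------------------------------------
# result serialization


def _fit_result_frames(obj: FitResult) -> tuple[pd.DataFrame, dict]:
    table = obj.coef.copy()
    meta = {
        "kind": "FitResult",
        "label": obj.label,
        "loglik": obj.loglik,
        "converged": obj.converged,
        "variance_components": obj.variance_components,
        "lrt": [dataclasses.asdict(r) for r in obj.lrt],
        "n_obs": obj.n_obs,
        "warnings": list(obj.warnings),
        "extra": obj.metadata,
    }
    return table, meta


def write_results(
    obj,
    path: str | Path,
    fmt: str = "csv",
    force: bool = False,
    metadata: dict | None = None,
) -> Path:
    """Write a result object as a delimited table plus a JSON sidecar.

    Refuses to overwrite an existing file unless ``force`` is given.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if (path.exists() or sidecar.exists()) and not force:
        raise FileExistsError(f"refusing to overwrite {path} (use force=True)")

    if isinstance(obj, FitResult):
        table, meta = _fit_result_frames(obj)
    elif isinstance(obj, MoranResult):
        table = pd.DataFrame([dataclasses.asdict(obj)])
        meta = {"kind": "MoranResult"}
    elif isinstance(obj, CoverageEstimate):
        table = pd.DataFrame([dataclasses.asdict(obj)])
        meta = {"kind": "CoverageEstimate"}
    elif (
        isinstance(obj, (list, tuple))
        and obj
        and isinstance(obj[0], BetaLevelSummary)
    ):
        table = pd.DataFrame([dataclasses.asdict(o) for o in obj])
        meta = {"kind": "BetaLevelSummaryList"}
    elif (
        isinstance(obj, (list, tuple))
        and obj
        and isinstance(obj[0], CoverageEstimate)
    ):
        table = pd.DataFrame([dataclasses.asdict(o) for o in obj])
        meta = {"kind": "CoverageEstimateList"}
    elif isinstance(obj, pd.DataFrame):
        table = obj
        meta = {"kind": "DataFrame"}
    else:
        raise TypeError(f"do not know how to serialize {type(obj).__name__}")

    meta["user_metadata"] = metadata or {}
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=sep, index=False)
    sidecar.write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def read_result(path: str | Path, fmt: str = "csv"):
    """Reconstruct a result object written by :func:`write_results`."""
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t"}[fmt]
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    table = pd.read_csv(path, sep=sep)
    kind = meta["kind"]
    if kind == "FitResult":
        return FitResult(
            label=meta["label"],
            coef=table,
            loglik=meta["loglik"],
            converged=meta["converged"],
            variance_components=meta["variance_components"],
            lrt=[LRTRecord(**r) for r in meta["lrt"]],
            n_obs=meta["n_obs"],
            warnings=meta["warnings"],
            metadata=meta["extra"],
        )
    if kind == "MoranResult":
        row = table.iloc[0].to_dict()
        return MoranResult(**{k: row[k] for k in ("i", "expected", "variance", "z", "p", "n")})
    if kind == "CoverageEstimate":
        row = table.iloc[0].to_dict()
        return CoverageEstimate(**row)
    if kind == "CoverageEstimateList":
        return [CoverageEstimate(**r) for r in table.to_dict("records")]
    if kind == "BetaLevelSummaryList":
        return [BetaLevelSummary(**r) for r in table.to_dict("records")]
    if kind == "DataFrame":
        return table
    raise ValueError(f"unknown result kind {kind!r}")
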