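"""Readers and writers for cell tables, region polygons, clinical tables and
expression matrices.

Conventions (fixed for the whole package):

* Coordinates are Cartesian microns, origin bottom-left, y increasing upward.
* Cell table CSV: mandatory header with ``cell_id``, ``x_um``, ``y_um``;
  optional ``compartment`` (one of ``tumor``/``stroma``/``unassigned``); every
  other column is a marker (binary 0/1 after gating, or a continuous
  intensity before gating). Comma delimiter, decimal point, UTF-8.
* Regions: GeoJSON FeatureCollection, one polygon feature per region with a
  ``label`` property in ``{tumor, stroma, tissue}``; coordinates in microns.
* Clinical CSV: ``sample_id``, ``time_months``, ``event`` plus covariates.
* Expression CSV: genes as rows, first column ``gene``, one column per sample,
  values on log scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape, mapping
from shapely.ops import unary_union

#: columns of a cell table that are never interpreted as markers
RESERVED_COLUMNS = frozenset({"cell_id", "x_um", "y_um", "compartment", "sample_id"})

REGION_LABELS = frozenset({"tumor", "stroma", "tissue"})

COMPARTMENTS = ("tumor", "stroma", "unassigned")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Marker columns of a cell table: every column not in the reserved set
    and not a phenotype flag added by :mod:`tlscape.phenotype`."""
    phenos = set(table.attrs.get("phenotype_columns", ()))
    return [c for c in table.columns
            if c not in RESERVED_COLUMNS and c not in phenos and c != "primary_label"]


def _validate_cell_table(table: pd.DataFrame, path=None) -> pd.DataFrame:
    where = f" in {path}" if path else ""
    for col in ("cell_id", "x_um", "y_um"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}{where}")
    dup = table["cell_id"].astype(str).duplicated()
    if dup.any():
        bad = table.loc[dup, "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id {bad!r}{where}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric or non-finite coordinate in column {col!r}, row {row}{where}")
        table[col] = vals.astype(float)
    if "compartment" in table.columns:
        bad = ~table["compartment"].isin(COMPARTMENTS)
        if bad.any():
            raise ValueError(
                f"unknown compartment {table.loc[bad, 'compartment'].iloc[0]!r}{where}")
    table["cell_id"] = table["cell_id"].astype(str)
    return table


def read_cell_table(path, marker_columns: list[str] | None = None,
                    sample_id: str | None = None) -> pd.DataFrame:
    """Read a per-cell coordinate/marker CSV into a validated DataFrame.

    Continuous marker columns are accepted and preserved for later gating;
    row order is preserved. ``marker_columns`` restricts which non-reserved
    columns are kept as markers (others are dropped).
    """
    path = Path(path)
    table = pd.read_csv(path)
    table = _validate_cell_table(table, path)
    if marker_columns is not None:
        missing = [m for m in marker_columns if m not in table.columns]
        if missing:
            raise ValueError(f"marker column(s) {missing} not present in {path}")
        keep = [c for c in table.columns
                if c in RESERVED_COLUMNS or c in marker_columns]
        table = table[keep]
    table.attrs["sample_id"] = sample_id or path.stem
    return table.reset_index(drop=True)


def write_cell_table(table: pd.DataFrame, path) -> None:
    """Write a cell table CSV. Deterministic: fixed column order (reserved
    first, then markers in current order), full-precision floats so that
    read∘write is the identity."""
    cols = [c for c in ("cell_id", "x_um", "y_um", "compartment") if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def _validate_ring(poly: Polygon, idx: int):
    if poly.is_empty or not poly.is_valid:
        raise ValueError(f"invalid (self-intersecting or degenerate) polygon at feature {idx}")


def read_regions(path) -> pd.DataFrame:
    """Read a GeoJSON FeatureCollection of labeled region polygons.

    Returns a DataFrame with columns ``label`` and ``geometry`` (shapely
    polygons, micron coordinates). Unknown labels and invalid rings are
    rejected.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    labels, geoms = [], []
    for i, feat in enumerate(gj.get("features", [])):
        label = feat.get("properties", {}).get("label")
        if label not in REGION_LABELS:
            raise ValueError(f"{path}: unknown region label {label!r} at feature {i}")
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"{path}: feature {i} is not a Polygon")
        _validate_ring(geom, i)
        labels.append(label)
        geoms.append(geom)
    regions = pd.DataFrame({"label": labels, "geometry": geoms})
    regions.attrs["sample_id"] = path.stem.removesuffix("_regions")
    return regions


def write_regions(regions: pd.DataFrame, path) -> None:
    feats = []
    for _, row in regions.iterrows():
        feats.append({
            "type": "Feature",
            "properties": {"label": row["label"]},
            "geometry": mapping(row["geometry"]),
        })
    gj = {"type": "FeatureCollection", "features": feats}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(gj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def assign_compartments(table: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Label each cell ``tumor`` if inside any tumor polygon, else ``stroma``
    if inside any stroma/tissue polygon, else ``unassigned``.

    A point on a polygon boundary counts as inside; tumor takes precedence
    over stroma on overlap (tumor nests sit inside the stroma).
    """
    if regions is None or len(regions) == 0:
        raise ValueError("regions must be non-empty; read an empty set as no-op upstream")
    out = table.copy()
    x = out["x_um"].to_numpy(float)
    y = out["y_um"].to_numpy(float)
    comp = np.full(len(out), "unassigned", dtype=object)
    stromal = unary_union(list(regions.loc[regions["label"].isin(["stroma", "tissue"]),
                                           "geometry"]))
    tumoral = unary_union(list(regions.loc[regions["label"] == "tumor", "geometry"]))
    if not stromal.is_empty:
        comp[shapely.intersects_xy(stromal, x, y)] = "stroma"
    if not tumoral.is_empty:
        comp[shapely.intersects_xy(tumoral, x, y)] = "tumor"
    out["compartment"] = comp
    out.attrs = dict(table.attrs)
    return out


def read_clinical(path) -> pd.DataFrame:
    """Clinical CSV: sample_id, time_months, event, covariates."""
    df = pd.read_csv(path)
    for col in ("sample_id", "time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"missing required clinical column {col!r} in {path}")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"event column must be 0/1 in {path}")
    if (df["time_months"] <= 0).any():
        raise ValueError(f"non-positive survival time in {path}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_expression(path) -> pd.DataFrame:
    """Expression CSV (genes x samples, log scale) into a DataFrame indexed
    by gene symbol."""
    df = pd.read_csv(path)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene symbol {dup!r} in {path}")
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError(f"non-finite expression value in {path}")
    return df.astype(float)


def write_expression(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path)
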