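"""Cell densities per compartment and tumor-contact profiles.

Densities are reported in cells/mm² (coordinates in μm; 1 mm² = 1e6 μm²).
With region polygons, the tumor area is the union of tumor polygons, the
stroma area the union of stroma/tissue polygons minus the tumor area (tumor
nests sit inside stroma), and the whole-section area their sum; without
regions, the whole-section area falls back to the convex hull of all cells
(flagged, because hulls overestimate sparse-section area) and per-compartment
densities are unavailable.

Contact profiles count (target, query) cell pairs in concentric distance
bins, the half-open convention [lo, hi) with the final bin closed, so no
pair is double-counted; ``close_fraction`` is the fraction of query cells
with at least one target strictly within 10 μm, matching the printed
"<10 μm" inequality. No edge correction is applied near section borders —
densities and contacts are raw, which is a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree, ConvexHull, QhullError
from shapely.ops import unary_union

UM2_PER_MM2 = 1e6


@dataclass
class ContactProfile:
    sample_id: str
    target_phenotype: str
    query_phenotype: str
    bin_edges: list[float]
    bin_counts: list[int]
    n_targets: int
    n_queries: int
    close_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": self.sample_id, "target": self.target_phenotype,
                 "query": self.query_phenotype, "bin_lo_um": lo, "bin_hi_um": hi,
                 "n_pairs": c}
                for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:],
                                     self.bin_counts)]
        return pd.DataFrame(rows)


def _pheno_mask(table: pd.DataFrame, phenotype: str) -> np.ndarray:
    if phenotype not in table.columns:
        raise ValueError(f"phenotype column {phenotype!r} not present; "
                         "run phenotype assignment first")
    return table[phenotype].to_numpy().astype(bool)


def _region_areas_mm2(regions: pd.DataFrame) -> dict[str, float]:
    tumoral = unary_union(list(regions.loc[regions["label"] == "tumor", "geometry"]))
    stromal = unary_union(list(regions.loc[regions["label"].isin(["stroma", "tissue"]),
                                           "geometry"]))
    tumor_area = tumoral.area / UM2_PER_MM2
    stroma_area = stromal.difference(tumoral).area / UM2_PER_MM2
    return {"tumor": tumor_area, "stroma": stroma_area,
            "whole": tumor_area + stroma_area}


def _hull_area_mm2(table: pd.DataFrame) -> float:
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(xy) < 3:
        raise ValueError("cannot compute hull area from fewer than 3 cells")
    try:
        hull = ConvexHull(xy)
    except QhullError as e:
        raise ValueError("degenerate (collinear) cell cloud: hull area is zero") from e
    return hull.volume / UM2_PER_MM2  # 2-D ConvexHull.volume is the area


def compute_densities(table: pd.DataFrame, regions: pd.DataFrame | None,
                      phenotypes: list[str]) -> pd.DataFrame:
    """Tidy density report: one row per compartment × phenotype with
    ``count`` and ``density_cells_per_mm2``.

    With regions, counts are split by the cells' ``compartment`` labels
    (tumor / stroma; the whole-section row also includes unassigned cells).
    Without regions only the ``whole`` compartment is reported, over the
    convex-hull area (``area_source`` column flags the fallback).
    """
    sample_id = table.attrs.get("sample_id", "")
    rows = []
    if regions is not None and len(regions) > 0:
        areas = _region_areas_mm2(regions)
        if areas["whole"] <= 0:
            raise ValueError("zero total region area")
        comp = table["compartment"] if "compartment" in table.columns else \
            pd.Series("unassigned", index=table.index)
        masks = {"tumor": (comp == "tumor").to_numpy(),
                 "stroma": (comp == "stroma").to_numpy(),
                 "whole": np.ones(len(table), dtype=bool)}
        source = "regions"
    else:
        areas = {"whole": _hull_area_mm2(table)}
        if areas["whole"] <= 0:
            raise ValueError("zero hull area")
        masks = {"whole": np.ones(len(table), dtype=bool)}
        source = "hull"
    for compartment, cmask in masks.items():
        area = areas[compartment]
        for ph in phenotypes:
            n = int((_pheno_mask(table, ph) & cmask).sum())
            rows.append({"sample_id": sample_id, "compartment": compartment,
                         "phenotype": ph, "count": n, "area_mm2": area,
                         "density_cells_per_mm2": n / area if area > 0 else np.nan,
                         "area_source": source})
    return pd.DataFrame(rows)


def contact_profile(table: pd.DataFrame, target_phenotype: str = "Tumor",
                    query_phenotype: str = "TCF1_PD1_CD8T",
                    bin_edges: list[float] = (0.0, 10.0, 20.0, 30.0),
                    close_um: float = 10.0) -> ContactProfile:
    """Count (target, query) pairs per distance bin and the fraction of query
    cells with a target in close proximity (< ``close_um``).

    Pairs are over distinct cells; a cell carrying both phenotypes never
    pairs with itself. Bins are [lo, hi), final bin inclusive of its upper
    edge; ``close_fraction`` uses strict ``<``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] != 0:
        raise ValueError("bin edges must start at 0")
    tmask = _pheno_mask(table, target_phenotype)
    qmask = _pheno_mask(table, query_phenotype)
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    tidx = np.flatnonzero(tmask)
    qidx = np.flatnonzero(qmask)
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_close = 0
    if len(tidx) and len(qidx):
        tree = cKDTree(xy[tidx])
        rmax = float(edges[-1])
        for qi in qidx:
            hits = tree.query_ball_point(xy[qi], rmax)
            hit_t = tidx[np.asarray(hits, dtype=int)] if hits else np.empty(0, int)
            hit_t = hit_t[hit_t != qi]  # a cell that is both target and query
            if len(hit_t) == 0:
                continue
            d = np.hypot(*(xy[hit_t] - xy[qi]).T)
            b = np.digitize(d, edges, right=False) - 1
            b[d == rmax] = len(counts) - 1  # final bin closed
            valid = (b >= 0) & (b < len(counts))
            np.add.at(counts, b[valid], 1)
            if (d < close_um).any():
                n_close += 1
    close_fraction = n_close / len(qidx) if len(qidx) else 0.0
    return ContactProfile(
        sample_id=table.attrs.get("sample_id", ""),
        target_phenotype=target_phenotype, query_phenotype=query_phenotype,
        bin_edges=list(edges), bin_counts=counts.tolist(),
        n_targets=int(len(tidx)), n_queries=int(len(qidx)),
        close_fraction=float(close_fraction))


def compare_groups(values_a, values_b) -> dict:
    """Two-sided Mann–Whitney U comparing two samples of densities/scores.

    Exact enumeration when both groups have fewer than 8 untied values,
    tie-corrected normal approximation otherwise. Two identical constant
    samples carry no evidence and return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return {"U": len(a) * len(b) / 2.0, "p": 1.0}
    ties = len(np.unique(pooled)) < len(pooled)
    if len(a) < 8 and len(b) < 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def fisher_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Fisher exact test on a 2×2 table [[a, b], [c, d]].

    Two-sided p sums hypergeometric tables no more probable than the
    observed one; odds ratio is ad/bc with 0 and inf for empty margins.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else (np.nan if a * d == 0 else odds)
    return {"odds_ratio": float(odds), "p": float(p)}
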