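"""Rule-based detection and maturity classification of tertiary lymphoid
structures (TLS) from cell centroids.

Candidate aggregates are the connected components of the cell contact graph
(an edge joins two cells whose centers are within ``contact_distance_um``).
Each component is then filtered, in a fixed order, by the inclusion rules —

1. size: at least ``min_cells`` member cells (default 51, i.e. more than 50);
2. extent: maximum pairwise center distance (Feret diameter) of at least
   ``min_extent_um`` (default 250 μm);
3. B-cell majority: CD20⁺ fraction strictly greater than
   ``b_majority_fraction`` (default 0.5);
4. presence of at least one CD4⁺ and one CD8⁺ T cell —

recording the first failed rule as the rejection reason. Survivors are
classified by follicular-dendritic-cell content: an aggregate with a
CD21⁺CD23⁺ cell carries a secondary follicle (``mTLS_secondary``), one with
CD21⁺ cells but no double positive a primary follicle (``mTLS_primary``),
and one with neither is an early TLS (``eTLS``).

The contact distance defaults to 13 μm center-to-center: a maximum
membrane-to-membrane gap of 3 μm plus a nominal 5 μm cell radius on each
side. A 3 μm *center* distance is physically impossible for ~10 μm cells, so
the center reading is rejected; the parameter makes the interpretation
explicit and tunable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree, ConvexHull, QhullError
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

ACCEPTED_STATUSES = ("eTLS", "mTLS_primary", "mTLS_secondary")


@dataclass
class TLSCall:
    """One candidate aggregate and its classification."""

    aggregate_id: int
    member_cell_ids: list[str]
    n_cells: int
    extent_um: float
    b_fraction: float
    n_cd4: int
    n_cd8: int
    n_cd21: int
    n_cd23: int
    n_cd21_cd23: int
    centroid: tuple[float, float]
    status: str

    @property
    def accepted(self) -> bool:
        return self.status in ACCEPTED_STATUSES

    def to_row(self) -> dict:
        d = asdict(self)
        d.pop("member_cell_ids")
        d["centroid_x_um"], d["centroid_y_um"] = d.pop("centroid")
        return d


def build_contact_graph(table: pd.DataFrame, contact_distance_um: float = 13.0
                        ) -> np.ndarray:
    """Edges (i, j), i < j, between cells whose center distance is at most
    ``contact_distance_um`` (inclusive). KD-tree backed; indices are row
    positions in ``table``."""
    if contact_distance_um <= 0:
        raise ValueError(f"contact_distance_um must be positive, got {contact_distance_um}")
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite cell coordinates")
    if len(xy) == 0:
        return np.empty((0, 2), dtype=np.intp)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=contact_distance_um, output_type="ndarray")
    return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]


def find_aggregates(edges: np.ndarray, n_cells: int) -> list[np.ndarray]:
    """Connected components of the contact graph, singletons included,
    ordered by their smallest member index (deterministic)."""
    if n_cells == 0:
        return []
    if len(edges) == 0:
        return [np.array([i]) for i in range(n_cells)]
    data = np.ones(len(edges), dtype=np.int8)
    adj = coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n_cells, n_cells))
    _, labels = _cc(adj, directed=False)
    order = np.argsort(labels, kind="stable")
    comps = np.split(order, np.flatnonzero(np.diff(labels[order])) + 1)
    comps.sort(key=lambda c: int(c.min()))
    return comps


def _extent(xy: np.ndarray) -> float:
    """Maximum pairwise distance (Feret diameter) of point centers."""
    if len(xy) < 2:
        return 0.0
    pts = xy
    if len(xy) > 50:
        try:
            pts = xy[ConvexHull(xy).vertices]
        except QhullError:  # collinear
            pass
    return float(pdist(pts).max())


def classify_aggregate(component: np.ndarray, table: pd.DataFrame,
                       aggregate_id: int = 0, *,
                       min_cells: int = 51, min_extent_um: float = 250.0,
                       b_majority_fraction: float = 0.5,
                       require_cd4: bool = True, require_cd8: bool = True,
                       maturity_rule: str = "follicle") -> TLSCall:
    """Apply the inclusion filters and maturity rules to one component.

    ``maturity_rule='follicle'``: any CD21⁺ cell makes the aggregate mature
    (CD21⁺CD23⁺ ⇒ secondary follicle). ``'strict_double_positive'``: maturity
    requires at least one CD21⁺CD23⁺ cell; CD21⁺-only aggregates stay early.
    """
    if len(component) == 0:
        raise ValueError("empty component")
    sub = table.iloc[component]
    xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
    n = len(sub)

    def count(marker):
        return int((sub[marker].to_numpy() == 1).sum()) if marker in sub.columns else 0

    cd20 = count("CD20")
    cd21 = (sub["CD21"].to_numpy() == 1) if "CD21" in sub.columns else np.zeros(n, bool)
    cd23 = (sub["CD23"].to_numpy() == 1) if "CD23" in sub.columns else np.zeros(n, bool)
    stats = dict(
        n_cells=n,
        extent_um=_extent(xy),
        b_fraction=cd20 / n,
        n_cd4=count("CD4"),
        n_cd8=count("CD8"),
        n_cd21=int(cd21.sum()),
        n_cd23=int(cd23.sum()),
        n_cd21_cd23=int((cd21 & cd23).sum()),
    )

    status = None
    if n < min_cells:
        status = "rejected:min_cells"
    elif stats["extent_um"] < min_extent_um:
        status = "rejected:min_extent"
    elif stats["b_fraction"] <= b_majority_fraction:
        status = "rejected:b_majority"
    elif require_cd4 and stats["n_cd4"] < 1:
        status = "rejected:no_cd4"
    elif require_cd8 and stats["n_cd8"] < 1:
        status = "rejected:no_cd8"
    elif maturity_rule == "follicle":
        if stats["n_cd21_cd23"] >= 1:
            status = "mTLS_secondary"
        elif stats["n_cd21"] >= 1:
            status = "mTLS_primary"
        else:
            status = "eTLS"
    elif maturity_rule == "strict_double_positive":
        status = "mTLS_secondary" if stats["n_cd21_cd23"] >= 1 else "eTLS"
    else:
        raise ValueError(f"unknown maturity_rule {maturity_rule!r}")

    return TLSCall(
        aggregate_id=aggregate_id,
        member_cell_ids=sub["cell_id"].astype(str).tolist(),
        centroid=(float(xy[:, 0].mean()), float(xy[:, 1].mean())),
        status=status,
        **stats,
    )


class TLSDetector(BaseEstimator, ClusterMixin):
    """Detect and classify tertiary lymphoid structures in a gated cell table.

    Parameters
    ----------
    contact_distance_um : float, default 13.0
        Maximum center-to-center distance for two cells to be in contact
        (3 μm membrane gap + 2 × 5 μm nominal cell radius).
    min_cells : int, default 51
        Minimum member count of an eligible aggregate (more than 50 cells).
    min_extent_um : float, default 250.0
        Minimum Feret diameter of an eligible aggregate.
    b_majority_fraction : float, default 0.5
        CD20⁺ member fraction must strictly exceed this.
    require_cd4, require_cd8 : bool, default True
        Require at least one CD4⁺ / CD8⁺ member.
    maturity_rule : {'follicle', 'strict_double_positive'}, default 'follicle'
        How follicular-dendritic-cell content maps to maturity.

    Attributes
    ----------
    calls_ : list of TLSCall
        Every component, accepted or rejected (auditability).
    labels_ : ndarray of int
        Per-cell accepted-TLS id, or -1 for cells not in an accepted TLS.
    summary_ : dict
        ``{"n_eTLS", "n_mTLS", "n_total_TLS"}``.
    """

    def __init__(self, contact_distance_um: float = 13.0, min_cells: int = 51,
                 min_extent_um: float = 250.0, b_majority_fraction: float = 0.5,
                 require_cd4: bool = True, require_cd8: bool = True,
                 maturity_rule: str = "follicle"):
        self.contact_distance_um = contact_distance_um
        self.min_cells = min_cells
        self.min_extent_um = min_extent_um
        self.b_majority_fraction = b_majority_fraction
        self.require_cd4 = require_cd4
        self.require_cd8 = require_cd8
        self.maturity_rule = maturity_rule

    def _validate(self):
        if self.contact_distance_um <= 0 or self.min_cells <= 0 or self.min_extent_um < 0:
            raise ValueError("detector lengths/counts must be positive")
        if not 0 < self.b_majority_fraction < 1:
            raise ValueError("b_majority_fraction must be in (0, 1)")
        if self.maturity_rule not in ("follicle", "strict_double_positive"):
            raise ValueError(f"unknown maturity_rule {self.maturity_rule!r}")

    def fit(self, X: pd.DataFrame, y=None):
        self._validate()
        edges = build_contact_graph(X, self.contact_distance_um)
        comps = find_aggregates(edges, len(X))
        calls = []
        labels = np.full(len(X), -1, dtype=int)
        next_id = 0
        for comp in comps:
            call = classify_aggregate(
                comp, X, aggregate_id=next_id,
                min_cells=self.min_cells, min_extent_um=self.min_extent_um,
                b_majority_fraction=self.b_majority_fraction,
                require_cd4=self.require_cd4, require_cd8=self.require_cd8,
                maturity_rule=self.maturity_rule)
            if call.accepted:
                labels[comp] = next_id
            calls.append(call)
            next_id += 1
        self.calls_ = calls
        self.labels_ = labels
        n_e = sum(c.status == "eTLS" for c in calls)
        n_m = sum(c.status in ("mTLS_primary", "mTLS_secondary") for c in calls)
        self.summary_ = {"n_eTLS": n_e, "n_mTLS": n_m, "n_total_TLS": n_e + n_m}
        return self

    def accepted_calls_(self) -> list[TLSCall]:
        return [c for c in self.calls_ if c.accepted]


def detect_tls(table: pd.DataFrame, **params) -> tuple[list[TLSCall], dict]:
    """Functional wrapper over :class:`TLSDetector`; returns (calls, summary)."""
    det = TLSDetector(**params).fit(table)
    return det.calls_, det.summary_


def calls_to_frame(calls: list[TLSCall]) -> pd.DataFrame:
    cols = ["aggregate_id", "n_cells", "extent_um", "b_fraction", "n_cd4", "n_cd8",
            "n_cd21", "n_cd23", "n_cd21_cd23", "centroid_x_um", "centroid_y_um", "status"]
    if not calls:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([c.to_row() for c in calls])[cols]
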