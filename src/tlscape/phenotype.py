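"""Marker gating and rule-based phenotype assignment.

A phenotype rule is a conjunction of required-positive and required-negative
marker flags (e.g. follicular helper T cells are CD4⁺CXCR5⁺PD1⁺FoxP3⁻).
Phenotypes are *multilabel*: a TCF1⁺PD1⁺CD8⁺ cell is also a PD1⁺CD8⁺ cell and
a CD8⁺ cell, and density reports count each population independently. A
single ``primary_label`` (lowest priority number wins) is added for
human-readable summaries only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RESERVED_COLUMNS, marker_columns


@dataclass(frozen=True)
class PhenotypeRule:
    """All ``require_pos`` markers must be 1 and all ``require_neg`` 0."""

    name: str
    require_pos: frozenset[str]
    require_neg: frozenset[str] = field(default_factory=frozenset)
    priority: int = 100

    def __post_init__(self):
        object.__setattr__(self, "require_pos", frozenset(self.require_pos))
        object.__setattr__(self, "require_neg", frozenset(self.require_neg))
        if self.require_pos & self.require_neg:
            raise ValueError(
                f"rule {self.name!r}: markers {sorted(self.require_pos & self.require_neg)} "
                "required both positive and negative")

    def matches(self, markers: dict) -> bool:
        return (all(markers.get(m, 0) == 1 for m in self.require_pos)
                and all(markers.get(m, 0) == 0 for m in self.require_neg))


def default_rules() -> list[PhenotypeRule]:
    """The package's built-in phenotype vocabulary for ovarian-cancer
    immune-contexture panels (PanCK tumor cells; CD8/CD4 T-cell states
    including progenitor-exhausted TCF1⁺PD1⁺CD8⁺ and terminally exhausted
    TIM-3⁺PD1⁺CD8⁺; T_FH; B cells; DC-LAMP⁺ dendritic cells; M2-like
    CD68⁺CD163⁺ macrophages; CD21⁺(CD23⁺) follicular dendritic cells).
    Shipped as ``data/default_rules.yaml``."""
    ref = importlib.resources.files("tlscape").joinpath("data/default_rules.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_rules(path)


def load_rules(path) -> list[PhenotypeRule]:
    """Load phenotype rules from YAML: a list of mappings with keys
    ``name``, ``require_pos``, optional ``require_neg`` and ``priority``."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = [PhenotypeRule(d["name"], frozenset(d.get("require_pos", [])),
                           frozenset(d.get("require_neg", [])),
                           int(d.get("priority", 100)))
             for d in raw]
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValueError(f"duplicate rule name {dup!r}")
    return rules


class MarkerGater(BaseEstimator, TransformerMixin):
    """Binarize continuous marker intensities at per-marker cutoffs.

    A marker value becomes 1 iff intensity >= cutoff (inclusive at the
    boundary); columns without a threshold — including already-binary
    columns — pass through unchanged.

    Parameters
    ----------
    thresholds : dict
        Map marker name -> cutoff.
    """

    def __init__(self, thresholds: dict | None = None):
        self.thresholds = thresholds

    def fit(self, X: pd.DataFrame, y=None):
        thresholds = self.thresholds or {}
        missing = [m for m in thresholds if m not in X.columns]
        if missing:
            raise ValueError(f"threshold given for missing column(s) {missing}")
        for m in thresholds:
            if not pd.api.types.is_numeric_dtype(X[m]):
                raise ValueError(f"column {m!r} is not numeric and cannot be gated")
        self.thresholds_ = dict(thresholds)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for m, cutoff in self.thresholds_.items():
            out[m] = (X[m].to_numpy(dtype=float) >= cutoff).astype(np.int64)
        out.attrs = dict(X.attrs)
        return out


class PhenotypeAssigner(BaseEstimator, TransformerMixin):
    """Add one boolean column per phenotype rule, plus a ``primary_label``.

    Rules are independent (multilabel); ``primary_label`` is the name of the
    matching rule with the lowest priority number, or ``"other"`` if none
    match. ``counts_`` summarizes matches per rule after ``transform``.

    Parameters
    ----------
    rules : list of PhenotypeRule, optional
        Defaults to :func:`default_rules`.
    """

    def __init__(self, rules: list[PhenotypeRule] | None = None):
        self.rules = rules

    def fit(self, X: pd.DataFrame, y=None):
        self.rules_ = list(self.rules) if self.rules is not None else default_rules()
        names = [r.name for r in self.rules_]
        if len(set(names)) != len(names):
            raise ValueError("duplicate rule names")
        markers = set(marker_columns(X))
        for r in self.rules_:
            unknown = (r.require_pos | r.require_neg) - markers
            if unknown:
                raise ValueError(
                    f"rule {r.name!r} references unknown marker(s) {sorted(unknown)}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        flags = {}
        for r in self.rules_:
            mask = np.ones(len(X), dtype=bool)
            for m in r.require_pos:
                mask &= X[m].to_numpy() == 1
            for m in r.require_neg:
                mask &= X[m].to_numpy() == 0
            flags[r.name] = mask
        for name, mask in flags.items():
            out[name] = mask
        by_priority = sorted(self.rules_, key=lambda r: (r.priority, r.name))
        primary = np.full(len(X), "other", dtype=object)
        unset = np.ones(len(X), dtype=bool)
        for r in by_priority:
            take = flags[r.name] & unset
            primary[take] = r.name
            unset &= ~take
        out["primary_label"] = primary
        out.attrs = dict(X.attrs)
        out.attrs["phenotype_columns"] = tuple(flags)
        self.counts_ = {name: int(mask.sum()) for name, mask in flags.items()}
        return out


def gate_markers(table: pd.DataFrame, thresholds: dict) -> pd.DataFrame:
    """Functional wrapper over :class:`MarkerGater`."""
    return MarkerGater(thresholds).fit(table).transform(table)


def assign_phenotypes(table: pd.DataFrame,
                      rules: list[PhenotypeRule] | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Functional wrapper over :class:`PhenotypeAssigner`; returns the
    augmented table and the per-rule match counts."""
    assigner = PhenotypeAssigner(rules).fit(table)
    out = assigner.transform(table)
    return out, assigner.counts_
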