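"""Metagene signature scoring (z-mean) and built-in gene sets.

A signature score for a sample is the mean, over the signature genes present
in the matrix, of that gene's z-score across samples (sample sd, ddof=1).
This is scale-free and matches common metagene practice; genes missing from
the matrix are dropped (a coverage fraction is reported), and constant gene
rows are dropped with a warning since they carry no contrast.

Built-ins: the endoplasmic-reticulum stress signature (DDIT3/CHOP, HSPA5/BiP,
HSP90B1) used to read out immunogenic-cell-death-associated ER stress, and a
12-chemokine signature of tertiary-lymphoid-structure formation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

_BUILTIN = {
    "ER_stress": ["DDIT3", "HSPA5", "HSP90B1"],
    "TLS_chemokine": ["CCL2", "CCL3", "CCL4", "CCL5", "CCL8", "CCL18",
                      "CCL19", "CCL21", "CXCL9", "CXCL10", "CXCL11", "CXCL13"],
}


def builtin_signatures() -> dict[str, list[str]]:
    """Copy of the built-in signature gene lists."""
    return {k: list(v) for k, v in _BUILTIN.items()}


def load_signatures(path) -> dict[str, list[str]]:
    """Load signatures from YAML: map name -> list of gene symbols.
    Duplicate symbols within a signature are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, genes in raw.items():
        genes = list(genes)
        if len(set(genes)) != len(genes):
            dup = next(g for g in genes if genes.count(g) > 1)
            raise ValueError(f"signature {name!r} lists gene {dup!r} more than once")
        out[name] = genes
    return out


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Score expression matrices (genes × samples, log scale) against gene
    signatures.

    ``fit`` records which signature genes are present and each present
    gene's mean/sd across the fitted samples; ``transform`` returns a
    samples × signatures score frame. ``coverage_`` maps signature name to
    the fraction of its genes found (after dropping constant rows).

    Parameters
    ----------
    signatures : dict, optional
        Map name -> gene list; defaults to :func:`builtin_signatures`.
    """

    def __init__(self, signatures: dict[str, list[str]] | None = None):
        self.signatures = signatures

    def fit(self, X: pd.DataFrame, y=None):
        sigs = self.signatures if self.signatures is not None else builtin_signatures()
        self.signatures_ = {k: list(v) for k, v in sigs.items()}
        self.gene_stats_ = {}
        self.coverage_ = {}
        for name, genes in self.signatures_.items():
            present = [g for g in genes if g in X.index]
            if not present:
                raise ValueError(
                    f"no gene of signature {name!r} present in the matrix: {genes}")
            usable = []
            for g in present:
                vals = X.loc[g].to_numpy(dtype=float)
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                if sd == 0.0:
                    warnings.warn(f"signature {name!r}: gene {g!r} is constant "
                                  "across samples; dropped", stacklevel=2)
                    continue
                usable.append((g, float(np.mean(vals)), sd))
            if not usable:
                raise ValueError(f"signature {name!r}: all present genes are constant")
            self.gene_stats_[name] = usable
            self.coverage_[name] = len(usable) / len(genes)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scores = {}
        for name, usable in self.gene_stats_.items():
            z = np.vstack([(X.loc[g].to_numpy(dtype=float) - mu) / sd
                           for g, mu, sd in usable])
            scores[name] = z.mean(axis=0)
        return pd.DataFrame(scores, index=X.columns)


def score_signature(matrix: pd.DataFrame, genes: list[str],
                    name: str = "signature") -> pd.Series:
    """Functional wrapper: z-mean score of one gene list on one matrix."""
    scorer = SignatureScorer({name: list(genes)}).fit(matrix)
    return scorer.transform(matrix)[name]
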