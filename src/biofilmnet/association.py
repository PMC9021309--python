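"""Association estimators over abundance tables.

This module houses the shared :class:`AssociationMatrix` container, the
centered log-ratio transform, the Spearman estimator, and the FDR-controlled
paired-feature correlation screen.  The compositional (SparCC-style) and
neighborhood-selection estimators live in :mod:`biofilmnet.sparcc` and
:mod:`biofilmnet.mb`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

log = logging.getLogger(__name__)

_METHODS = ("spearman", "sparcc", "mb", "ensemble")


@dataclass
class AssociationMatrix:
    """Symmetric taxon-by-taxon association scores from one estimator.

    Spearman, SparCC and ensemble matrices have entries in [-1, 1] with unit
    diagonal; MB (neighborhood-selection) matrices are normalized to [-1, 1]
    with zero diagonal.
    """

    values: np.ndarray
    taxon_ids: list[str]
    method: str
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        p = len(self.taxon_ids)
        if self.values.shape != (p, p):
            raise ValueError("association matrix must be square over the taxon set")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("association matrix must be symmetric")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("association entries must lie in [-1, 1]")
        diag = np.diag(self.values)
        if self.method == "mb":
            if not np.allclose(diag, 0.0):
                raise ValueError("mb matrix must have zero diagonal")
        else:
            if not np.allclose(diag, 1.0):
                raise ValueError(f"{self.method} matrix must have unit diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.taxon_ids)

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path, method: str, n_samples: int = 0) -> "AssociationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index), method, n_samples)


def clr_transform(table: AbundanceTable, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform, per sample column.

    Each column becomes ``log(x + pseudocount)`` minus the column's mean log,
    removing the compositional sum constraint; every transformed column sums
    to zero.
    """
    x = table.values
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(x == 0):
        raise ValueError("zero abundances require a positive pseudocount")
    logs = np.log(x + pseudocount)
    return logs - logs.mean(axis=0, keepdims=True)


def spearman_matrix(table: AbundanceTable) -> AssociationMatrix:
    """Pairwise Spearman rank correlation of taxa across samples.

    Ties receive average (mid) ranks.  A constant taxon has no rank variance;
    its associations are recorded as 0 (with a warning) so that downstream
    ensemble averaging stays total.
    """
    if table.n_samples < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    ranks = stats.rankdata(table.values, axis=1)  # average ranks on ties
    constant = ranks.std(axis=1) == 0
    if constant.any():
        log.warning("%d constant taxa: associations set to 0", int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.nan_to_num(rho, nan=0.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return AssociationMatrix(rho, list(table.taxon_ids), "spearman", table.n_samples)


def _stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


@dataclass
class FeatureCorrelationReport:
    """All cross-table Spearman correlations with BH-adjusted p-values.

    ``pairs`` has one row per (feature_a, feature_b) with columns
    ``rho, p_raw, p_adjusted, stars``; stars follow the *<0.05, **<0.01,
    ***<0.001 convention on the adjusted p.
    """

    pairs: pd.DataFrame
    q_threshold: float

    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["p_adjusted"] < self.q_threshold]

    def write_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _as_feature_frame(table) -> pd.DataFrame:
    if isinstance(table, AbundanceTable):
        return table.to_frame()
    return pd.DataFrame(table)


def correlate_features(table_a, table_b, q: float = 0.05) -> FeatureCorrelationReport:
    """Spearman screen of every cross-table feature pair with BH control.

    Both tables are features-by-samples (``AbundanceTable`` or DataFrame) and
    must cover the same sample set.  Two-sided p-values for all
    ``n_a * n_b`` pairs are Benjamini-Hochberg adjusted jointly.
    """
    a = _as_feature_frame(table_a)
    b = _as_feature_frame(table_b)
    if set(a.columns) != set(b.columns):
        raise ValueError("feature tables must share the same sample set")
    b = b[a.columns]
    n = a.shape[1]
    if n < 5:
        raise ValueError("feature correlation needs at least 5 shared samples")

    res = stats.spearmanr(a.to_numpy().T, b.to_numpy().T)
    rho = np.atleast_2d(res.statistic)
    pval = np.atleast_2d(res.pvalue)
    na, nb = a.shape[0], b.shape[0]
    cross_rho = rho[:na, na:]
    cross_p = pval[:na, na:]
    cross_rho = np.nan_to_num(cross_rho, nan=0.0)
    cross_p = np.nan_to_num(cross_p, nan=1.0)

    flat_p = cross_p.ravel()
    _, p_adj, _, _ = multipletests(flat_p, method="fdr_bh")
    rows = []
    for i, fa in enumerate(a.index):
        for j, fb in enumerate(b.index):
            k = i * nb + j
            rows.append((fa, fb, cross_rho[i, j], flat_p[k], p_adj[k], _stars(p_adj[k])))
    pairs = pd.DataFrame(
        rows, columns=["feature_a", "feature_b", "rho", "p_raw", "p_adjusted", "stars"]
    )
    return FeatureCorrelationReport(pairs=pairs, q_threshold=q)
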