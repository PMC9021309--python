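"""Sparse graph inference by neighborhood selection with StARS.

Meinshausen–Bühlmann estimation: after a CLR transform, each taxon is
regressed on all others with an L1 penalty; an edge is declared where the
regression coefficient is nonzero, merged across the two node-wise fits by
an AND or OR rule.  The penalty is chosen by StARS (Stability Approach to
Regularization Selection): over random subsamples, the densest graph on the
penalty path whose monotonized average edge instability stays at or below
the target instability is selected.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.linear_model import lasso_path

from ._rng import stage_rng
from .association import AssociationMatrix, clr_transform
from .tables import AbundanceTable

log = logging.getLogger(__name__)


def default_lambda_path(X: np.ndarray, n_lambda: int = 20, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing penalty path over [ratio * lambda_max, lambda_max].

    ``lambda_max`` is the smallest penalty at which every neighborhood
    regression is empty: max over taxon pairs of |cov| of the centered data.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    G = np.abs(Xc.T @ Xc) / n
    np.fill_diagonal(G, 0.0)
    lam_max = float(G.max())
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def _neighborhood_coefs(X: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Lasso coefficients for each node regressed on the rest.

    Returns array of shape (n_alphas, p, p): entry [a, i, j] is the
    coefficient of taxon j in taxon i's regression (diagonal zero).
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0, keepdims=True)
    out = np.zeros((len(alphas), p, p))
    idx = np.arange(p)
    for i in range(p):
        others = idx[idx != i]
        _, coefs, _ = lasso_path(Xc[:, others], Xc[:, i], alphas=alphas)
        # lasso_path returns (n_features, n_alphas) in the order of `alphas`
        out[:, i, others] = coefs.T
    return out


def _adjacency(coefs: np.ndarray, merge_rule: str) -> np.ndarray:
    """Merge node-wise supports into symmetric adjacencies (bool, per alpha)."""
    nz = coefs != 0.0
    if merge_rule == "OR":
        return nz | np.transpose(nz, (0, 2, 1))
    return nz & np.transpose(nz, (0, 2, 1))


def stars_select(
    X: np.ndarray,
    lambda_path: np.ndarray,
    n_subsamples: int,
    ratio: float,
    instability_threshold: float,
    merge_rule: str,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """StARS penalty selection.

    Returns the index into ``lambda_path`` of the selected penalty and the
    monotonized instability curve.  The path is scanned from the sparse end
    (largest penalty); the selected penalty is the smallest one whose
    running-supremum instability is still at or below the threshold — the
    densest graph that is stable across subsamples.
    """
    n, p = X.shape
    b = max(2, int(np.floor(ratio * n)))
    freq = np.zeros((len(lambda_path), p, p))
    for _ in range(n_subsamples):
        rows = rng.choice(n, size=b, replace=False)
        adj = _adjacency(_neighborhood_coefs(X[rows], lambda_path), merge_rule)
        freq += adj
    theta = freq / n_subsamples
    xi = 2.0 * theta * (1.0 - theta)
    iu = np.triu_indices(p, k=1)
    instab = xi[:, iu[0], iu[1]].mean(axis=1)
    instab_mono = np.maximum.accumulate(instab)
    ok = np.flatnonzero(instab_mono <= instability_threshold)
    if len(ok) == 0:  # even the sparsest graph is unstable
        return 0, instab_mono
    return int(ok[-1]), instab_mono


def mb_network(
    table: AbundanceTable,
    lambda_path: np.ndarray | None = None,
    stars_subsamples: int = 50,
    stars_ratio: float = 0.8,
    instability_threshold: float = 0.05,
    merge_rule: str = "OR",
    seed: int = 0,
    pseudocount: float = 1.0,
) -> AssociationMatrix:
    """Neighborhood-selection association matrix with StARS-selected penalty.

    Edge weights are the sign-preserving symmetrized lasso coefficients at
    the selected penalty, normalized by the maximum absolute coefficient so
    entries lie in [-1, 1] (zero diagonal), making the matrix commensurate
    with correlation-type estimators for ensemble averaging.
    """
    if table.n_samples < 8:
        raise ValueError("neighborhood selection needs at least 8 samples")
    if merge_rule not in ("AND", "OR"):
        raise ValueError("merge_rule must be 'AND' or 'OR'")
    X = clr_transform(table, pseudocount=pseudocount).T  # samples x taxa
    if lambda_path is None:
        lambda_path = default_lambda_path(X)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if len(lambda_path) > 1 and np.any(np.diff(lambda_path) >= 0):
        raise ValueError("lambda_path must be strictly decreasing")

    rng = stage_rng(seed, "mb_stars")
    if len(lambda_path) == 1:
        sel = 0
    else:
        sel, _ = stars_select(
            X, lambda_path, stars_subsamples, stars_ratio,
            instability_threshold, merge_rule, rng,
        )

    coefs = _neighborhood_coefs(X, lambda_path)[sel]
    support = _adjacency(coefs[None], merge_rule)[0]
    W = (coefs + coefs.T) / 2.0
    W[~support] = 0.0
    np.fill_diagonal(W, 0.0)
    wmax = np.abs(W).max()
    if wmax == 0:
        log.warning("neighborhood selection produced an empty graph")
    else:
        W = W / wmax
    return AssociationMatrix(W, list(table.taxon_ids), "mb", table.n_samples)
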