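"""SparCC-style compositional correlation.

Estimates correlations between the unobserved "basis" abundances behind a
compositional count table.  For taxa i, j the log-ratio variance
``t_ij = Var log(x_i / x_j)`` decomposes as

    t_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

with basis variances ``w``.  Assuming the correlation network is sparse, the
cross terms are dropped and the basis variances solve the linear system
``[(D-2) I + J] w = t``, where ``t`` holds the row sums of the log-ratio
variance matrix and J is the all-ones matrix.  Correlations are then

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)),

clipped to [-1, 1].  The most strongly correlated pair violating the
sparsity assumption is iteratively removed from the system and the variances
re-solved.  Uncertainty in the observed fractions is handled by resampling
fractions from a per-sample Dirichlet posterior over the counts and taking
the median correlation across resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import stage_rng
from .association import AssociationMatrix
from .tables import AbundanceTable

log = logging.getLogger(__name__)

_OMEGA_FLOOR = 1e-12


@dataclass
class SparccState:
    """Internal quantities of one SparCC solve.

    ``T`` is the log-ratio variance matrix (t_ij), ``omega`` the solved
    basis variances (w_i), ``excluded_pairs`` the taxon-index pairs removed
    during the iterative sparsity refinement.
    """

    T: np.ndarray
    omega: np.ndarray
    excluded_pairs: set[tuple[int, int]] = field(default_factory=set)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = Var over samples of log(x_i / x_j), from samples-x-taxa fractions."""
    logx = np.log(fractions)
    V = np.cov(logx, rowvar=False)
    V = np.atleast_2d(V)
    d = np.diag(V)
    T = d[:, None] + d[None, :] - 2.0 * V
    T = np.clip(T, 0.0, None)
    np.fill_diagonal(T, 0.0)
    return T


def _solve_basis(T: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    D = T.shape[0]
    M = np.ones((D, D)) + (D - 2) * np.eye(D)
    t = T.sum(axis=1)
    for i, j in excluded:
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        t[i] -= T[i, j]
        t[j] -= T[i, j]
    omega = np.linalg.solve(M, t)
    return np.clip(omega, _OMEGA_FLOOR, None)


def _correlations(T: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - T) / denom
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def _sparcc_once(
    fractions: np.ndarray, n_inner: int, exclusion_threshold: float
) -> tuple[np.ndarray, SparccState]:
    T = log_ratio_variances(fractions)
    excluded: set[tuple[int, int]] = set()
    omega = _solve_basis(T, excluded)
    rho = _correlations(T, omega)
    for _ in range(n_inner):
        cand = np.abs(rho.copy())
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        omega = _solve_basis(T, excluded)
        rho = _correlations(T, omega)
    return rho, SparccState(T=T, omega=omega, excluded_pairs=excluded)


def _dirichlet_fractions(
    counts: np.ndarray, pseudocount: float, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet-posterior fraction draw per sample (samples x taxa)."""
    alpha = counts.T + pseudocount  # samples x taxa
    g = rng.standard_gamma(alpha)
    return g / g.sum(axis=1, keepdims=True)


def sparcc(
    table: AbundanceTable,
    n_inner: int = 10,
    exclusion_threshold: float = 0.1,
    n_resamples: int = 20,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> tuple[AssociationMatrix, SparccState]:
    """Basis correlations of a compositional count table.

    ``n_resamples`` Dirichlet-posterior fraction draws are each run through
    the sparsity-approximated solve with up to ``n_inner`` strong-pair
    exclusions at ``exclusion_threshold``; the reported correlation is the
    element-wise median over resamples.  With ``n_resamples=0`` the point
    estimate on pseudocount-smoothed observed fractions is returned.
    The returned state comes from the point solve on smoothed fractions.
    """
    if table.n_taxa < 4:
        raise ValueError(
            "SparCC needs at least 4 taxa: the basis-variance system is "
            "underdetermined below that"
        )
    if table.n_samples < 10:
        log.warning("SparCC with %d samples; >= 10 recommended", table.n_samples)
    counts = table.values
    if n_resamples > 0 and table.kind != "counts":
        raise ValueError("Dirichlet resampling requires a count table")

    point_fracs = (counts + pseudocount).T
    point_fracs = point_fracs / point_fracs.sum(axis=1, keepdims=True)
    rho_point, state = _sparcc_once(point_fracs, n_inner, exclusion_threshold)

    if n_resamples == 0:
        rho = rho_point
    else:
        rng = stage_rng(seed, "sparcc")
        draws = np.empty((n_resamples, table.n_taxa, table.n_taxa))
        for k in range(n_resamples):
            fr = _dirichlet_fractions(counts, pseudocount, rng)
            draws[k], _ = _sparcc_once(fr, n_inner, exclusion_threshold)
        rho = np.median(draws, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    mat = AssociationMatrix(rho, list(table.taxon_ids), "sparcc", table.n_samples)
    return mat, state
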