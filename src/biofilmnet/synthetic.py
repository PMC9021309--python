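"""Synthetic abundance tables with known ground truth.

Four generators cover the inputs the downstream stages consume:

* :func:`simulate_compositional` — logistic-normal/multinomial count tables
  with a planted latent correlation structure spanning labeled domains, the
  positive control for the association estimators.
* :func:`simulate_neutral` — communities assembled under Sloan's neutral
  drift–migration model at a known migration rate ``m``.
* :func:`simulate_source_sink` — neutral target communities seeded from an
  existing source table's metacommunity.
* :func:`simulate_paired_features` — paired feature tables with planted
  monotone dependencies for the FDR-controlled correlation screen.

All generators are pure functions of their arguments including ``seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._rng import stage_rng
from .tables import AbundanceTable, Lineage

log = logging.getLogger(__name__)

DOMAINS = ("Bacteria", "Archaea", "Eukaryota")

_EIG_TOL = 1e-8


@dataclass
class SyntheticTruth:
    """Ground truth recorded by a generator run.

    ``latent_correlation`` is the taxon-by-taxon correlation of the latent
    log-abundances; ``planted_adjacency`` is the support of its precision
    matrix — the conditional-dependence graph a neighborhood-selection
    estimator targets (for equicorrelated blocks this coincides with the
    nonzero off-diagonal correlations).  ``true_m`` is set only by the
    neutral generators.
    """

    latent_correlation: np.ndarray
    planted_adjacency: np.ndarray
    domain_labels: dict[str, str]
    seed: int
    true_m: float | None = None
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        R = np.asarray(self.latent_correlation, dtype=float)
        A = np.asarray(self.planted_adjacency)
        if not np.allclose(R, R.T, atol=1e-9):
            raise ValueError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("latent_correlation must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-6:
            raise ValueError("latent_correlation must be positive semidefinite")
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("planted_adjacency must be symmetric with zero diagonal")
        self.latent_correlation = R
        self.planted_adjacency = A.astype(int)

    def write_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "true_m": self.true_m,
            "domain_labels": self.domain_labels,
            "latent_correlation": self.latent_correlation.tolist(),
            "planted_adjacency": self.planted_adjacency.tolist(),
            "planted_pairs": [list(p) for p in self.planted_pairs],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ----------------------------------------------------------------------
# correlation specifications
# ----------------------------------------------------------------------

def block_correlation(n_taxa: int, blocks: list[tuple[int, float]] | None = None) -> np.ndarray:
    """Correlation matrix with equicorrelated diagonal blocks.

    ``blocks`` lists (size, within-block correlation) pairs laid out from
    taxon 0; remaining taxa are uncorrelated.
    """
    R = np.eye(n_taxa)
    pos = 0
    for size, rho in blocks or []:
        if not -1.0 < rho < 1.0:
            raise ValueError(f"within-block correlation must be in (-1, 1), got {rho}")
        if pos + size > n_taxa:
            raise ValueError("block sizes exceed n_taxa")
        if size > 1 and rho < -1.0 / (size - 1):
            raise ValueError(
                f"equicorrelation {rho} on a block of {size} is not positive semidefinite"
            )
        R[pos:pos + size, pos:pos + size] = rho
        np.fill_diagonal(R[pos:pos + size, pos:pos + size], 1.0)
        pos += size
    return R


def chain_correlation(n_taxa: int, k: int, rho: float) -> np.ndarray:
    """Correlation matrix whose first *k* taxa form an AR(1) chain.

    Entry (i, j) within the chain is ``rho**|i-j|``; the precision matrix is
    tridiagonal, so the conditional-dependence graph is exactly the k-node
    path — the natural ground truth for neighborhood selection.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("chain correlation must be in (-1, 1)")
    R = np.eye(n_taxa)
    idx = np.arange(k)
    R[:k, :k] = rho ** np.abs(idx[:, None] - idx[None, :])
    return R


def _precision_support(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Off-diagonal support of the precision matrix (conditional dependence)."""
    w = np.linalg.eigvalsh(R)
    if w.min() > 1e-10:
        P = np.linalg.inv(R)
    else:  # PSD but singular: fall back to correlation support
        P = R.copy()
    A = (np.abs(P) > tol).astype(int)
    np.fill_diagonal(A, 0)
    return A


def _check_correlation(R: np.ndarray, n_taxa: int) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (n_taxa, n_taxa):
        raise ValueError(f"correlation matrix shape {R.shape} != ({n_taxa}, {n_taxa})")
    if not np.allclose(R, R.T, atol=1e-9):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -_EIG_TOL:
        raise ValueError(
            f"correlation matrix is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    return R


def default_taxonomy(n_taxa: int, prefix: str = "T") -> dict[str, Lineage]:
    """Deterministic taxonomy by index stride: every 5th taxon Eukaryota,
    every 5th-minus-one Archaea, the rest Bacteria; phyla cycle with period 4
    within each domain."""
    tax = {}
    for i in range(n_taxa):
        if i % 5 == 4:
            dom = "Eukaryota"
        elif i % 5 == 3:
            dom = "Archaea"
        else:
            dom = "Bacteria"
        tax[f"{prefix}{i:04d}"] = Lineage(
            domain=dom, phylum=f"{dom[:3]}_phylum_{i % 4}"
        )
    return tax


def _taxon_ids(n_taxa: int, prefix: str = "T") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n_taxa)]


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------

def simulate_compositional(
    n_samples: int,
    n_taxa: int,
    corr_spec=None,
    depth: int = 10_000,
    seed: int = 0,
    mean_sd: float = 1.0,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Logistic-normal -> multinomial count table with planted correlations.

    Latent log-abundances are multivariate normal with the correlation given
    by ``corr_spec`` (``None`` for identity, a list of ``(size, rho)`` blocks,
    or an explicit correlation matrix); per-sample fractions are the softmax
    of the latent values plus taxon-specific lognormal mean offsets; counts
    are one multinomial draw of ``depth`` reads per sample.
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be >= 4")
    if depth < n_taxa:
        raise ValueError(f"depth {depth} < n_taxa {n_taxa}")
    if depth < 10 * n_taxa:
        log.warning("depth %d is below 10 x n_taxa; counts will be very sparse", depth)
    if corr_spec is None:
        R = np.eye(n_taxa)
    elif isinstance(corr_spec, (list, tuple)):
        R = block_correlation(n_taxa, list(corr_spec))
    else:
        R = _check_correlation(corr_spec, n_taxa)

    rng = stage_rng(seed, "simulate_compositional")
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_samples, n_taxa)) @ L.T
    mu = rng.normal(0.0, mean_sd, size=n_taxa)  # abundance skew; correlations untouched
    logits = z + mu
    logits -= logits.max(axis=1, keepdims=True)
    fractions = np.exp(logits)
    fractions /= fractions.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depth, fractions)  # (n_samples, n_taxa)

    ids = _taxon_ids(n_taxa)
    table = AbundanceTable(
        counts.T.astype(float), ids, [f"S{j:03d}" for j in range(n_samples)],
        kind="counts", taxonomy=default_taxonomy(n_taxa),
    )
    truth = SyntheticTruth(
        latent_correlation=R,
        planted_adjacency=_precision_support(R),
        domain_labels={t: lin.domain for t, lin in table.taxonomy.items()},
        seed=seed,
    )
    return table, truth


def _neutral_counts(
    p: np.ndarray, n_samples: int, N_reads: int, m: float, rng: np.random.Generator
) -> np.ndarray:
    """Beta local abundances + multinomial allocation of N_reads per sample."""
    a = N_reads * m * p
    b = N_reads * m * (1.0 - p)
    x = rng.beta(a[None, :], b[None, :], size=(n_samples, len(p)))
    x = np.clip(x, 0.0, None)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    counts = rng.multinomial(N_reads, x / totals)
    return counts.T.astype(float)  # taxa x samples


def simulate_neutral(
    n_taxa: int = 1000,
    n_samples: int = 50,
    N_reads: int = 10_000,
    m: float = 0.1,
    abundance_dist: tuple[float, float] = (0.0, 2.0),
    seed: int = 0,
) -> tuple[AbundanceTable, SyntheticTruth]:
    """Neutrally assembled local communities at migration rate *m*.

    Metacommunity relative abundances are lognormal(meanlog, sdlog),
    renormalized.  Each sample's local relative abundance for taxon *i* is a
    Beta(N·m·p_i, N·m·(1-p_i)) draw; reads are then allocated by a single
    multinomial of ``N_reads`` over the (normalized) local abundances, so
    per-sample totals equal ``N_reads`` exactly.
    """
    if not 0.0 < m <= 1.0:
        raise ValueError(f"migration rate m must be in (0, 1], got {m}")
    if N_reads * m < 1.0:
        raise ValueError("N_reads * m must be >= 1")
    meanlog, sdlog = abundance_dist
    rng = stage_rng(seed, "simulate_neutral")
    p = rng.lognormal(meanlog, sdlog, size=n_taxa)
    p /= p.sum()
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    values = _neutral_counts(p, n_samples, N_reads, m, rng)

    ids = _taxon_ids(n_taxa)
    table = AbundanceTable(
        values, ids, [f"S{j:03d}" for j in range(n_samples)],
        kind="counts", taxonomy=default_taxonomy(n_taxa),
    )
    truth = SyntheticTruth(
        latent_correlation=np.eye(n_taxa),
        planted_adjacency=np.zeros((n_taxa, n_taxa), dtype=int),
        domain_labels={t: lin.domain for t, lin in table.taxonomy.items()},
        seed=seed,
        true_m=m,
    )
    return table, truth


def simulate_source_sink(
    source: AbundanceTable,
    m: float,
    n_target_samples: int,
    N_reads: int = 10_000,
    seed: int = 0,
) -> AbundanceTable:
    """Neutral target communities whose metacommunity is the source's mean
    relative abundance; taxon set identical to the source."""
    if source.n_samples < 1:
        raise ValueError("source table must have at least one sample")
    if n_target_samples < 1:
        raise ValueError("n_target_samples must be >= 1")
    if not 0.0 < m <= 1.0:
        raise ValueError(f"migration rate m must be in (0, 1], got {m}")
    rel = source.relative().values
    p = rel.mean(axis=1)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    p /= p.sum()
    rng = stage_rng(seed, "simulate_source_sink")
    values = _neutral_counts(p, n_target_samples, N_reads, m, rng)
    return AbundanceTable(
        values, list(source.taxon_ids),
        [f"sink{j:03d}" for j in range(n_target_samples)],
        kind="counts", taxonomy=source.taxonomy,
    )


@dataclass
class PairedFeatureTruth:
    """Planted monotone dependencies between two feature tables."""

    planted_pairs: list[tuple[str, str, float]]
    seed: int


def simulate_paired_features(
    n_samples: int,
    n_features_a: int,
    n_features_b: int,
    planted_pairs: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
):
    """Two positive feature tables (features x samples) with planted
    monotone dependencies.

    Each planted pair ``(i, j, strength)`` makes B-feature *j* share a latent
    Gaussian driver with A-feature *i* at the given correlation; all other
    pairs are independent.  A monotone exp transform maps features to
    positive abundances (rank correlations are unchanged).
    """
    import pandas as pd

    planted_pairs = planted_pairs or []
    seen = set()
    for i, j, s in planted_pairs:
        if not -1.0 <= s <= 1.0:
            raise ValueError(f"planted strength must be in [-1, 1], got {s}")
        if (i, j) in seen:
            raise ValueError(f"duplicate planted pair ({i}, {j})")
        seen.add((i, j))
    if len({j for _, j, _ in planted_pairs}) < len(planted_pairs):
        raise ValueError("a B-feature may appear in at most one planted pair")

    rng = stage_rng(seed, "simulate_paired_features")
    A = rng.standard_normal((n_samples, n_features_a))
    B = rng.standard_normal((n_samples, n_features_b))
    named_pairs = []
    for i, j, s in planted_pairs:
        B[:, j] = s * A[:, i] + np.sqrt(max(0.0, 1.0 - s * s)) * rng.standard_normal(n_samples)
        named_pairs.append((f"A{i:03d}", f"B{j:03d}", float(s)))

    samples = [f"S{k:03d}" for k in range(n_samples)]
    table_a = pd.DataFrame(
        np.exp(A).T, index=[f"A{i:03d}" for i in range(n_features_a)], columns=samples
    )
    table_b = pd.DataFrame(
        np.exp(B).T, index=[f"B{j:03d}" for j in range(n_features_b)], columns=samples
    )
    return table_a, table_b, PairedFeatureTruth(named_pairs, seed)
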