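"""Sloan neutral community model: occurrence-frequency fits and source-sink tests.

Under neutral drift–migration balance, the local relative abundance of a
taxon with metacommunity relative abundance ``p`` in a community of ``N``
individuals with immigration probability ``m`` follows a
Beta(N·m·p, N·m·(1-p)) distribution.  The probability of detecting the
taxon (local abundance above the detection limit ``d``, one read by
default) is therefore

    freq(p) = 1 - BetaCDF(d; N·m·p, N·m·(1-p)).

Fitting minimizes the squared error between observed occurrence frequencies
and this prediction over ``m``; the generalized R² (1 - SSE/SST, allowed to
go negative) measures how well neutral assembly explains the
occurrence-abundance relationship.  In the source–sink variant the
metacommunity abundances come from a putative source community while the
occurrence frequencies come from the target: a low or negative R² argues
against the target being neutrally assembled from that source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from .tables import AbundanceTable

log = logging.getLogger(__name__)


def predict_frequency(p, N: float, m: float, d: float):
    """Neutral prediction of occurrence frequency for metacommunity abundance p.

    ``1 - BetaCDF(d; N·m·p, N·m·(1-p))`` — the probability that a taxon's
    local relative abundance exceeds the detection limit ``d``.  Vectorized
    over ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("metacommunity abundances p must lie strictly in (0, 1)")
    if N * m <= 0:
        raise ValueError("N * m must be positive")
    if not 0 < d < 1:
        raise ValueError("detection limit d must lie in (0, 1)")
    a = N * m * p
    b = N * m * (1.0 - p)
    return stats.beta.sf(d, a, b)


def predict_frequency_reads(p, N: float, m: float, n_reads: float):
    """Detection-aware neutral prediction: probability of observing >= 1 read.

    Marginalizing the Beta local abundance over binomial read sampling at
    depth ``n_reads``, the taxon's count is Beta-binomial and the presence
    probability is ``1 - B(a, b + n_reads) / B(a, b)`` with
    ``a = N·m·p, b = N·m·(1-p)``.  This is the appropriate prediction when
    presence is defined on counts, where a sharp threshold at ``d`` ignores
    the sampling noise around the detection limit.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("metacommunity abundances p must lie strictly in (0, 1)")
    if N * m <= 0 or n_reads <= 0:
        raise ValueError("N * m and n_reads must be positive")
    a = N * m * p
    b = N * m * (1.0 - p)
    log_p0 = gammaln(b + n_reads) + gammaln(a + b) - gammaln(b) - gammaln(a + b + n_reads)
    return -np.expm1(log_p0)


@dataclass
class NeutralFit:
    """Result of a Sloan neutral-model fit.

    ``taxa`` holds one row per fitted taxon: metacommunity abundance ``p``,
    observed and predicted occurrence frequency, 95% Wilson binomial bounds
    around the prediction, and the partition label (above/within/below the
    neutral band).
    """

    m: float
    N: float
    d: float
    r_squared: float
    n_samples: int
    taxa: pd.DataFrame
    at_bound: bool = False

    @property
    def partition_counts(self) -> dict[str, int]:
        return self.taxa["partition"].value_counts().to_dict()

    def write_json(self, path) -> None:
        payload = {
            "m": self.m,
            "N": self.N,
            "d": self.d,
            "r_squared": self.r_squared,
            "n_samples": self.n_samples,
            "n_taxa": int(len(self.taxa)),
            "at_bound": self.at_bound,
            "partition_counts": {k: int(v) for k, v in self.partition_counts.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    def write_tsv(self, path) -> None:
        self.taxa.to_csv(path, sep="\t", index=False, float_format="%.8g")


_M_LO = 1e-6


def _predictor(detection: str, d: float, n_reads: float):
    if detection == "threshold":
        return lambda p, N, m: predict_frequency(p, N, m, d)
    if detection == "reads":
        return lambda p, N, m: predict_frequency_reads(p, N, m, n_reads)
    raise ValueError("detection must be 'reads' or 'threshold'")


def _fit_m(p: np.ndarray, freq_obs: np.ndarray, N: float, predict) -> tuple[float, bool]:
    """Bounded scalar least squares for m.

    The 1-D objective can be flat near the bounds, so a log-spaced grid scan
    brackets the optimum before a bounded refinement.
    """

    def sse(m: float) -> float:
        pred = predict(p, N, m)
        return float(np.sum((freq_obs - pred) ** 2))

    grid = np.geomspace(_M_LO, 1.0, 60)
    vals = np.array([sse(m) for m in grid])
    k = int(vals.argmin())
    lo = grid[max(0, k - 1)]
    hi = grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(
        sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    best_m = float(res.x) if res.fun <= vals[k] else float(grid[k])
    at_bound = best_m <= _M_LO * 1.01 or best_m >= 1.0 - 1e-9
    if at_bound:
        log.warning("neutral fit: m estimate at bound (m=%.3g)", best_m)
    return best_m, at_bound


def _assemble_fit(
    p: np.ndarray,
    freq_obs: np.ndarray,
    taxa: list[str],
    N: float,
    d: float,
    n_samples: int,
    predict,
    ci_level: float = 0.95,
) -> NeutralFit:
    if np.all(freq_obs >= 1.0):
        raise ValueError(
            "all taxa occur in every sample: occurrence frequencies carry no "
            "information to fit m"
        )
    m_hat, at_bound = _fit_m(p, freq_obs, N, predict)
    pred = predict(p, N, m_hat)
    sse = float(np.sum((freq_obs - pred) ** 2))
    sst = float(np.sum((freq_obs - freq_obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")

    lo, hi = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=1 - ci_level, method="wilson"
    )
    partition = np.where(freq_obs > hi, "above", np.where(freq_obs < lo, "below", "within"))
    df = pd.DataFrame(
        {
            "taxon_id": taxa,
            "p": p,
            "freq_obs": freq_obs,
            "freq_pred": pred,
            "ci_lower": lo,
            "ci_upper": hi,
            "partition": partition,
        }
    )
    return NeutralFit(
        m=m_hat, N=float(N), d=float(d), r_squared=float(r2),
        n_samples=n_samples, taxa=df, at_bound=at_bound,
    )


def _prepare(table: AbundanceTable, d: float | None, N: float | None):
    rel = table.relative().values
    totals = table.sample_totals()
    if N is None:
        if table.kind == "relative":
            raise ValueError("N (individuals per sample) must be given for relative tables")
        N = float(totals.mean())
    if d is None:
        d = 1.0 / N
    present = rel.max(axis=1) > 0
    return rel, present, float(N), float(d)


def occurrence_frequency(rel: np.ndarray, d: float) -> np.ndarray:
    """Fraction of samples where relative abundance reaches the detection limit."""
    return (rel >= d - 1e-12).mean(axis=1)


def fit_ncm(
    table: AbundanceTable, d: float | None = None, N: float | None = None,
    ci_level: float = 0.95, detection: str = "reads",
) -> NeutralFit:
    """Fit the Sloan neutral model to one community table.

    ``N`` defaults to the mean per-sample total count and ``d`` to one read
    (1/N).  Metacommunity abundances are mean relative abundances across
    samples; occurrence frequency is presence (abundance >= d) across
    samples.  m is estimated by bounded nonlinear least squares.

    ``detection`` chooses the predicted-frequency model: ``"reads"``
    (default) uses the Beta-binomial probability of observing at least one
    read, matching count-based presence; ``"threshold"`` uses the sharp
    Beta-tail prediction :func:`predict_frequency` at detection limit ``d``.
    """
    if table.n_samples < 5:
        raise ValueError("neutral fit needs at least 5 samples")
    rel, present, N, d = _prepare(table, d, N)
    if present.sum() < 10:
        raise ValueError("neutral fit needs at least 10 taxa present in >= 1 sample")
    p = rel[present].mean(axis=1)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    freq_obs = occurrence_frequency(rel[present], d)
    taxa = [t for t, keep in zip(table.taxon_ids, present) if keep]
    predict = _predictor(detection, d, N)
    return _assemble_fit(p, freq_obs, taxa, N, d, table.n_samples, predict, ci_level)


def source_sink_fit(
    source: AbundanceTable,
    target: AbundanceTable,
    d: float | None = None,
    N: float | None = None,
    ci_level: float = 0.95,
    detection: str = "reads",
) -> NeutralFit:
    """Source→sink neutral fit: source abundances predict target occurrence.

    Identical to :func:`fit_ncm` except the metacommunity abundance of each
    taxon is its mean relative abundance in the *source* community, while
    occurrence frequencies (and N, d defaults) come from the *target*.  A
    low or negative R² is evidence against the target being neutrally
    assembled from the source.
    """
    if target.n_samples < 5:
        raise ValueError("source-sink fit needs at least 5 target samples")
    shared = [t for t in source.taxon_ids if t in set(target.taxon_ids)]
    if not shared:
        raise ValueError("no shared taxa between source and target tables")
    frac = len(shared) / len(set(source.taxon_ids) | set(target.taxon_ids))
    if frac < 0.5:
        log.warning("only %.0f%% taxon overlap between source and target", 100 * frac)

    src_rel = source.relative().to_frame().loc[shared].to_numpy()
    tgt = target
    tgt_idx = [tgt.taxon_ids.index(t) for t in shared]
    rel, _, N, d = _prepare(tgt, d, N)
    rel = rel[tgt_idx]

    p = src_rel.mean(axis=1)
    keep = p > 0
    if keep.sum() < 10:
        raise ValueError("fewer than 10 shared taxa present in the source")
    p = np.clip(p[keep], 1e-12, 1 - 1e-12)
    freq_obs = occurrence_frequency(rel[keep], d)
    taxa = [t for t, k in zip(shared, keep) if k]
    predict = _predictor(detection, d, N)
    return _assemble_fit(p, freq_obs, taxa, N, d, tgt.n_samples, predict, ci_level)
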