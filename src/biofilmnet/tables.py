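"""Abundance tables and taxonomy metadata.

The central container is :class:`AbundanceTable`, a taxa-by-samples matrix of
counts or relative abundances, optionally annotated with a taxonomy map
(domain through genus).  Tables are read and written as plain TSV: first
column taxon IDs, header row sample IDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Lineage:
    """Taxonomic lineage from domain down to genus; missing ranks are 'unclassified'."""

    domain: str = UNCLASSIFIED
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED

    def rank(self, name: str) -> str:
        key = "class_" if name == "class" else name
        return getattr(self, key)

    @classmethod
    def from_fields(cls, fields: list[str]) -> "Lineage":
        vals = []
        for i in range(6):
            v = fields[i].strip() if i < len(fields) else ""
            if not v or v.upper() == "NA":
                v = UNCLASSIFIED
            vals.append(v)
        return cls(*vals)


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix.

    Parameters
    ----------
    values : ndarray of shape (n_taxa, n_samples)
        Non-negative abundances.
    taxon_ids, sample_ids : sequences of unique identifiers.
    kind : ``"counts"`` or ``"relative"``.
    taxonomy : optional mapping taxon ID -> :class:`Lineage`.
    """

    values: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    kind: str = "counts"
    taxonomy: dict[str, Lineage] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D taxa x samples matrix")
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.kind == "relative":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("relative-abundance columns must sum to 1 +/- 1e-6")

    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def relative(self) -> "AbundanceTable":
        """Return a copy normalized so each sample column sums to 1."""
        sums = self.values.sum(axis=0)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize: some sample has zero total abundance")
        return AbundanceTable(
            self.values / sums,
            list(self.taxon_ids),
            list(self.sample_ids),
            kind="relative",
            taxonomy=self.taxonomy,
        )

    def sample_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceTable(
            self.values[:, idx], list(self.taxon_ids), list(sample_ids),
            kind=self.kind, taxonomy=self.taxonomy,
        )

    def domain_labels(self) -> dict[str, str]:
        if self.taxonomy is None:
            return {}
        return {t: lin.domain for t, lin in self.taxonomy.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    # ------------------------------------------------------------------
    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t", float_format="%.12g")


def read_abundance_tsv(path) -> AbundanceTable:
    """Read a taxa-by-samples abundance TSV.

    First column holds taxon IDs, the header row sample IDs.  ``kind`` is
    inferred: all-integer values -> counts; columns summing to ~1 -> relative.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate taxon IDs in {path}: {dups}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance values in {path}: {exc}") from exc
    if np.isnan(values).any():
        rows = [df.index[i] for i in np.unique(np.where(np.isnan(values))[0])]
        raise ValueError(f"missing/ragged values in {path} at taxa {rows}")
    if (values < 0).any():
        rows = [df.index[i] for i in np.unique(np.where(values < 0)[0])]
        raise ValueError(f"negative abundances in {path} at taxa {rows}")
    colsums = values.sum(axis=0)
    if np.allclose(values, np.round(values)) and not np.allclose(colsums, 1.0, atol=1e-6):
        kind = "counts"
    elif np.allclose(colsums, 1.0, atol=1e-6):
        kind = "relative"
    else:
        kind = "counts"
    return AbundanceTable(values, list(df.index), list(df.columns), kind=kind)


def read_taxonomy_tsv(path, known_taxa: list[str] | None = None) -> dict[str, Lineage]:
    """Read a taxonomy TSV with columns taxon_id, domain..genus ('NA' allowed).

    Returns a map taxon -> :class:`Lineage`; missing ranks become
    'unclassified'.  Taxa absent from *known_taxa* (when given) are kept but
    reported in a warning.
    """
    tax: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        log.warning("taxonomy file %s is empty", path)
        return tax
    start = 0
    first = lines[0].split("\t")
    if first and first[0].strip().lower() in ("taxon_id", "taxon", "id", "mag"):
        start = 1
    for ln in lines[start:]:
        parts = ln.split("\t")
        taxon = parts[0].strip()
        tax[taxon] = Lineage.from_fields(parts[1:])
    if known_taxa is not None:
        extra = sorted(set(tax) - set(known_taxa))
        if extra:
            log.warning("taxonomy lists %d taxa absent from the abundance table: %s",
                        len(extra), extra[:10])
    return tax


def write_taxonomy_tsv(path, taxonomy: dict[str, Lineage]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\t" + "\t".join(RANKS) + "\n")
        for taxon in sorted(taxonomy):
            lin = taxonomy[taxon]
            fh.write(taxon + "\t" + "\t".join(lin.rank(r) for r in RANKS) + "\n")
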