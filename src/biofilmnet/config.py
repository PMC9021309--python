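"""Pipeline configuration: defaults, YAML round-trip, resolution."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class SyntheticSpec:
    """Synthetic-input specification for a pipeline run."""

    kind: str = "compositional"  # compositional | neutral
    n_samples: int = 60
    n_taxa: int = 30
    blocks: list[list] = field(default_factory=lambda: [[5, 0.8]])
    depth: int = 10_000
    # neutral-kind parameters
    m: float = 0.1
    N_reads: int = 10_000


@dataclass
class SparccOptions:
    n_inner: int = 10
    exclusion_threshold: float = 0.1
    n_resamples: int = 20
    pseudocount: float = 1.0


@dataclass
class MbOptions:
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    stars_subsamples: int = 50
    stars_ratio: float = 0.8
    instability_threshold: float = 0.05
    merge_rule: str = "OR"
    pseudocount: float = 1.0


@dataclass
class EnsembleOptions:
    weights: list[float] | None = None
    edge_threshold: float = 0.3


@dataclass
class NullOptions:
    enabled: bool = True
    families: list[str] = field(default_factory=lambda: ["ER", "BA", "SBM"])
    R: int = 1000
    block_by: str = "phylum"
    centrality_stats: bool = True


@dataclass
class NcmOptions:
    enabled: bool = True
    d: float | None = None
    ci_level: float = 0.95


@dataclass
class PipelineConfig:
    """Fully-resolved configuration of one pipeline run.

    Either ``abundance_tsv`` (with optional ``taxonomy_tsv`` and
    ``sample_filter``) or ``synthetic`` must be set.  The resolved config is
    written beside the outputs; identical resolved config + seed implies
    byte-identical numeric outputs.
    """

    abundance_tsv: str | None = None
    taxonomy_tsv: str | None = None
    sample_filter: list[str] | None = None
    synthetic: SyntheticSpec | None = None
    sparcc: SparccOptions = field(default_factory=SparccOptions)
    mb: MbOptions = field(default_factory=MbOptions)
    ensemble: EnsembleOptions = field(default_factory=EnsembleOptions)
    nulls: NullOptions = field(default_factory=NullOptions)
    ncm: NcmOptions = field(default_factory=NcmOptions)
    out_dir: str = "runs/run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.abundance_tsv is None) == (self.synthetic is None):
            raise ValueError("exactly one of abundance_tsv or synthetic must be set")
        if self.ensemble.edge_threshold < 0:
            raise ValueError("edge_threshold must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (
            ("synthetic", SyntheticSpec),
            ("sparcc", SparccOptions),
            ("mb", MbOptions),
            ("ensemble", EnsembleOptions),
            ("nulls", NullOptions),
            ("ncm", NcmOptions),
        ):
            if raw.get(key) is not None and not isinstance(raw[key], sub):
                raw[key] = sub(**raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
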