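"""End-to-end pipeline: input/simulation -> association -> ensemble graph ->
pruning -> centralities -> null models -> neutral fit, with all artifacts
written to a run directory."""

from __future__ import annotations

import logging
import time
from pathlib import Path

from . import synthetic
from .association import spearman_matrix
from .config import PipelineConfig
from .mb import mb_network
from .network import (
    build_graph,
    centralities,
    cross_domain_edges,
    ensemble_average,
    largest_component,
    prune,
)
from .neutral import fit_ncm
from .nullmodels import compare_to_nulls
from .sparcc import sparcc
from .tables import AbundanceTable, read_abundance_tsv, read_taxonomy_tsv

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_input(cfg: PipelineConfig, out: Path) -> AbundanceTable:
    if cfg.synthetic is not None:
        spec = cfg.synthetic
        if spec.kind == "compositional":
            blocks = [tuple(b) for b in (spec.blocks or [])]
            table, truth = synthetic.simulate_compositional(
                n_samples=spec.n_samples, n_taxa=spec.n_taxa,
                corr_spec=blocks or None, depth=spec.depth, seed=cfg.seed,
            )
        elif spec.kind == "neutral":
            table, truth = synthetic.simulate_neutral(
                n_taxa=spec.n_taxa, n_samples=spec.n_samples,
                N_reads=spec.N_reads, m=spec.m, seed=cfg.seed,
            )
        else:
            raise ValueError(f"unknown synthetic kind {spec.kind!r}")
        truth.write_json(out / "truth.json")
        table.write_tsv(out / "abundance.tsv")
        return table
    table = read_abundance_tsv(cfg.abundance_tsv)
    if cfg.taxonomy_tsv:
        table.taxonomy = read_taxonomy_tsv(cfg.taxonomy_tsv, known_taxa=table.taxon_ids)
    if cfg.sample_filter:
        table = table.subset_samples(cfg.sample_filter)
    return table


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full pipeline; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure remain on disk next to an ``INVALID`` marker.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stage = "setup"
    timings: list[tuple[str, float]] = []
    try:
        t0 = time.perf_counter()

        stage = "input"
        table = _load_input(cfg, out)
        timings.append((stage, time.perf_counter() - t0))

        stage = "association"
        t0 = time.perf_counter()
        mats = []
        sp = spearman_matrix(table)
        sp.write_tsv(out / "association_spearman.tsv")
        mats.append(sp)
        if table.kind == "counts":
            sc, _ = sparcc(
                table, n_inner=cfg.sparcc.n_inner,
                exclusion_threshold=cfg.sparcc.exclusion_threshold,
                n_resamples=cfg.sparcc.n_resamples,
                pseudocount=cfg.sparcc.pseudocount, seed=cfg.seed,
            )
            sc.write_tsv(out / "association_sparcc.tsv")
            mats.append(sc)
        else:
            log.info("relative-abundance input: SparCC stage skipped (needs counts)")
        mbm = mb_network(
            table, stars_subsamples=cfg.mb.stars_subsamples,
            stars_ratio=cfg.mb.stars_ratio,
            instability_threshold=cfg.mb.instability_threshold,
            merge_rule=cfg.mb.merge_rule, seed=cfg.seed,
            pseudocount=cfg.mb.pseudocount,
        )
        mbm.write_tsv(out / "association_mb.tsv")
        mats.append(mbm)
        timings.append((stage, time.perf_counter() - t0))

        stage = "ensemble"
        t0 = time.perf_counter()
        ens = ensemble_average(mats, weights=cfg.ensemble.weights)
        ens.write_tsv(out / "association_ensemble.tsv")
        graph = build_graph(ens, cfg.ensemble.edge_threshold, table.taxonomy)
        graph.write_graphml(out / "graph_full.graphml")
        graph.write_edgelist_tsv(out / "graph_full_edges.tsv")
        pruned = prune(graph)
        pruned.write_graphml(out / "graph_pruned.graphml")
        pruned.write_edgelist_tsv(out / "graph_pruned_edges.tsv")
        comp = largest_component(pruned)
        comp.write_graphml(out / "graph_largest_component.graphml")
        comp.write_edgelist_tsv(out / "graph_largest_component_edges.tsv")
        cent = centralities(comp)
        cent.write_tsv(out / "centralities.tsv")
        if table.taxonomy:
            cross_domain_edges(comp).to_csv(
                out / "cross_domain_edges.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        timings.append((stage, time.perf_counter() - t0))

        stage = "null_models"
        t0 = time.perf_counter()
        if cfg.nulls.enabled and comp.n_nodes >= 3 and comp.n_edges >= 2:
            report = compare_to_nulls(
                comp, families=tuple(cfg.nulls.families), R=cfg.nulls.R,
                block_by=cfg.nulls.block_by, seed=cfg.seed,
                centrality_stats=cfg.nulls.centrality_stats,
            )
            report.write_json(out / "null_models.json")
            report.replicate_table().to_csv(
                out / "null_replicates.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
        else:
            log.info("null-model stage skipped: graph too small "
                     "(%d nodes, %d edges)", comp.n_nodes, comp.n_edges)
        timings.append((stage, time.perf_counter() - t0))

        stage = "neutral_fit"
        t0 = time.perf_counter()
        if cfg.ncm.enabled and table.kind == "counts":
            try:
                fit = fit_ncm(table, d=cfg.ncm.d, ci_level=cfg.ncm.ci_level)
                fit.write_json(out / "neutral_fit.json")
                fit.write_tsv(out / "neutral_fit_taxa.tsv")
            except ValueError as exc:
                log.info("neutral-fit stage skipped: %s", exc)
        timings.append((stage, time.perf_counter() - t0))

        stage = "finalize"
        cfg.to_yaml(out / "config_resolved.yaml")
        with open(out / "run.log", "w", encoding="utf-8") as fh:
            fh.write(f"seed\t{cfg.seed}\n")
            for name, dt in timings:
                fh.write(f"{name}\t{dt:.3f}s\n")
        return out
    except Exception as exc:
        (out / "INVALID").write_text(f"failed at stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc
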