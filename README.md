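# biofilmnet

Cross-domain co-occurrence network inference and neutral community model
fitting for microbial abundance tables, as used in stream-biofilm
metagenomics.

Microbial communities in extreme habitats such as glacier-fed streams are
studied through abundance tables of metagenome-assembled genomes (MAGs) or
amplicon taxa across samples. Two recurring questions are: *which taxa
co-occur beyond what composition and chance explain* — spanning bacteria,
archaea and eukaryotes — and *whether a community is neutrally assembled
from a regional pool or a neighboring habitat* (e.g. boulder biofilms seeded
from sandy-sediment biofilms). `biofilmnet` implements the statistical core
for both, plus a synthetic-data generator with known ground truth so every
stage has a recovery test without any sequencing data.

## What it computes

**Ensemble co-occurrence networks.** Three association estimators are
averaged element-wise:

* Spearman rank correlation *r*<sub>s</sub> across samples;
* SparCC-style compositional correlation: from log-ratio variances
  *t*<sub>ij</sub> = Var log(*x*<sub>i</sub>/*x*<sub>j</sub>), basis variances ω solve the
  sparsity-approximated system [(D−2)I + J] ω = t, and
  ρ<sub>ij</sub> = (ω<sub>i</sub> + ω<sub>j</sub> − t<sub>ij</sub>) / (2√(ω<sub>i</sub>ω<sub>j</sub>)), with iterative
  exclusion of strongly correlated pairs and Dirichlet resampling;
* Meinshausen–Bühlmann neighborhood selection on CLR-transformed data with
  the StARS stability criterion choosing the lasso penalty.

The averaged matrix is thresholded into a graph; negative edges are removed
and nodes of degree < 2 discarded to a fixpoint (the 2-core), leaving the
mutualistic core whose largest component is scored by degree and
node/edge betweenness. Matched Erdős–Rényi, Barabási–Albert and
stochastic-block null ensembles test whether the degree distribution is
non-random (a heavy tail against ER nulls is the preferential-attachment
signature).

**Sloan neutral community model.** A taxon with metacommunity relative
abundance *p* in a local community of *N* individuals with migration
probability *m* has local abundance Beta(*Nmp*, *Nm*(1−*p*)); its predicted
occurrence frequency above a detection limit *d* is
1 − BetaCDF(*d*; *Nmp*, *Nm*(1−*p*)). Fitting *m* by bounded least squares
against observed occurrence frequencies yields the migration rate and a
generalized R² (negative values allowed — they signal rejection). The
source→sink variant takes *p* from a putative source community and the
occurrence frequencies from the target. For count tables the default fit
uses the detection-aware Beta-binomial prediction of observing ≥ 1 read
(see `docs/methods.md`).

**FDR-controlled feature screen.** All cross-table Spearman correlations
(e.g. eukaryotic producers × enzyme classes) with joint Benjamini–Hochberg
adjustment and `*`/`**`/`***` stars at 0.05/0.01/0.001.

## Worked example

```python
import biofilmnet as bn

table, truth = bn.simulate_compositional(
    n_samples=120, n_taxa=25, corr_spec=[(5, 0.8)], depth=10_000, seed=42)

spearman = bn.spearman_matrix(table)
sparcc_mat, _ = bn.sparcc(table, seed=42)
mb_mat = bn.mb_network(table, stars_subsamples=30, seed=42)
ensemble = bn.ensemble_average([spearman, sparcc_mat, mb_mat])

graph = bn.build_graph(ensemble, edge_threshold=0.3, taxonomy=table.taxonomy)
core = bn.largest_component(bn.prune(graph))
```

prints (via `examples/01_compositional_network.py`):

```
ensemble weight inside block : 0.628
ensemble weight outside block: 0.047
graph: 25 nodes / 10 edges -> mutualistic core: 5 nodes / 10 edges
cross-domain edges in core: 7 of 10
```

The planted 5-taxon correlated block (spanning bacterial, archaeal and
eukaryotic labels) is the only structure surviving pruning: its averaged
associations (~0.63) sit far above the background (~0.05), and the
mutualistic core is exactly the block, complete with cross-domain edges.

The neutral fit (`examples/03_neutral_fit.py`) recovers a planted migration
rate of 0.1 as `m = 0.0998` with `R² = 0.974`, and the source→sink controls
(`examples/04_source_sink.py`) give `R² = 0.916` for a genuinely neutral
target versus `R² = -0.785` after permuting taxa — the rejection signature.

One script per capability lives in `examples/`; the `biofilmnet` CLI
(`simulate`, `associate`, `network`, `nulls`, `ncm`, `run`) exposes the same
pipeline from the shell with YAML configs and a mandatory seed.

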