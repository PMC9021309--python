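# Methods

This note documents the models, estimators, defaults and numerical choices
behind `biofilmnet`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic data

**Compositional tables.** Latent log-abundances are multivariate normal
with a user-specified correlation matrix (identity, equicorrelated blocks,
or an explicit matrix such as an AR(1) chain); taxon-specific mean offsets
(lognormal, sd 1) create a realistic rank-abundance skew. Per-sample
fractions are the softmax of the latent values; counts are a single
multinomial draw per sample at the requested depth (default 10,000 reads),
so column sums are exact. The recorded ground truth is the latent
correlation matrix and, as the planted adjacency, the support of its
precision matrix — the conditional-dependence graph that a
neighborhood-selection estimator targets. For equicorrelated blocks this
coincides with the nonzero correlations; for an AR(1) chain it is exactly
the path, which is why chains are used for edge-recovery scoring.
Domain/phylum labels are assigned deterministically by taxon-index stride
(every 5th taxon Eukaryota, every 5th−1 Archaea, rest Bacteria), so
cross-domain fixtures are reproducible.

**Neutral communities.** Metacommunity abundances are lognormal
(meanlog 0, sdlog 2), renormalized — a realistic long-tailed rank-abundance
curve. Each sample's local relative abundance per taxon is a
Beta(N·m·p, N·m·(1−p)) draw (Sloan drift–migration equilibrium); reads are
then allocated by one multinomial of N_reads (default 10,000, a typical
rarefied depth) over the normalized local abundances, so per-sample totals
are exact and each sample exposes its latent relative-abundance vector.
With ~1000 taxa the normalization perturbs per-taxon marginals negligibly
(the Beta vector's sum has sd ≈ 0.01). The source→sink generator is the
same process with the metacommunity replaced by the source table's mean
relative abundances.

**Paired features.** Planted pairs share a latent Gaussian driver at the
stated correlation; a monotone exp transform maps features to positive
abundances without touching rank correlations. All unplanted pairs are
independent.

What these generators do **not** emulate: phylogenetic correlation of
abundances, sample-depth heterogeneity, batch effects, taxa absent from the
reference (unbinned reads), or zero-inflation beyond what the logistic
normal/Beta sampling produces. Passing recovery tests therefore shows the
estimators are correct and calibrated under their own assumptions, not that
real biofilm networks are recovered at any particular accuracy.

## Association estimators

**Spearman** uses average (mid) ranks; constant taxa have undefined rank
correlation and are recorded as 0 with a warning so ensemble averaging
stays total.

**SparCC-style compositional correlation.** Log-ratio variances
t_ij = Var log(x_i/x_j) are computed from fractions; basis variances solve
the sparsity-approximated linear system [(D−2)I + J]ω = t (row sums t).
Correlations ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j)) are clipped to [−1,1].
Up to `n_inner = 10` iterations, the most strongly correlated remaining
pair with |ρ| above `exclusion_threshold = 0.1` is removed from the system
and ω re-solved (the sparsity assumption breaks for such pairs). Count
uncertainty: `n_resamples = 20` Dirichlet-posterior fraction draws per
sample (pseudocount 1), final ρ is the element-wise median; the reported
internal state (T, ω, exclusions) comes from the point solve on smoothed
observed fractions. These defaults follow the algorithm's reference
settings. At least 4 taxa are required — below that the basis-variance
system is underdetermined. On identity simulations the estimate agrees with
plain Pearson correlation of log counts to < 0.1 mean absolute difference,
the expected large-D uncorrelated limit.

**Neighborhood selection (MB) with StARS.** Data are CLR-transformed
(pseudocount 1) and each taxon regressed on all others with the lasso over
a path of 20 penalties log-spaced on [0.01·λ_max, λ_max], where λ_max is
the largest absolute empirical covariance (the smallest penalty giving
all-empty neighborhoods). StARS draws `stars_subsamples = 50` subsamples of
80% of samples, computes per-pair edge frequencies θ over subsamples per
penalty, and the average instability 2θ(1−θ) over all pairs; after
monotonizing the instability curve from the sparse end, the **densest**
penalty whose instability stays ≤ 0.05 is selected. (Selecting the sparsest
such penalty would trivially return the empty graph at λ_max, whose
instability is 0.) Edges merge across the two node-wise fits by OR
(default); weights are the sign-preserving symmetrized coefficients
normalized by the maximum absolute coefficient, making the matrix
commensurate with correlation-type estimators before averaging. Edge
recovery is scored against the planted conditional-dependence graph; at the
small dimensions used in the tests (p = 15) single-run F1 fluctuates with
the subsample draw, so recovery is reported as a mean over seeds.

**Feature screen.** Spearman rho and two-sided p for every cross-table
pair; Benjamini–Hochberg over all pairs jointly; stars at adjusted
p < 0.05/0.01/0.001.

## Graph construction, pruning, centralities

Edges join pairs with |averaged weight| ≥ τ (default τ = 0.3, exposed in
config; a deliberate choice in the absence of a canonical threshold).
Pruning removes negative edges first, then iterates away nodes of degree
< 2 to the fixpoint — the 2-core of the positive subgraph. The order
matters: filtering degrees before dropping negative edges could retain
nodes whose support is purely antagonistic, contradicting the goal of
keeping mutualistic cliques of three or more interactions. The largest
component breaks size ties by edge count, then by smallest member ID, so
results are deterministic. Centralities use unweighted shortest paths
(association weights are affinities, not distances): node betweenness
normalized by (n−1)(n−2)/2, edge betweenness raw. Both are verified against
exhaustive shortest-path enumeration.

## Null models

ER nulls are G(n, M) with the observed edge count exactly; BA nulls grow
from a star seed with m_attach = round(M/n) and are re-matched to exactly M
edges by uniform random edge deletion/addition, keeping density out of the
comparison; SBM nulls take blocks from a node attribute (default phylum; a
degree-median split when absent) with probabilities estimated from observed
within/between densities. The test statistic is the KS distance between the
observed degree distribution and the pooled null degrees; the empirical
p-value is (1 + #{replicate KS ≥ observed KS})/(R + 1), each replicate
scored against the leave-one-out pool so replicate and observed scores are
exchangeable under the null. z-scores on mean degree and mean node/edge
betweenness are reported alongside (mean degree is matched by construction
for ER/BA, so its z is ≈ 0 there). Default R = 1000; R < 20 is rejected
(p resolution). Calibration: an ER draw tested against ER nulls is
non-significant at 0.05 in ≈ 95% of seeds; power: a BA(300, 2) graph is
flagged at p < 0.01.

## Sloan neutral model

`predict_frequency` is the Beta-tail prediction
1 − BetaCDF(d; Nmp, Nm(1−p)). The fit takes N as the mean per-sample total,
d = 1/N (one read) by default, p as mean relative abundance, occurrence as
presence (relative abundance ≥ d, i.e. ≥ 1 read) across samples, and
minimizes squared error over m ∈ (0, 1] by a log-spaced grid scan plus
bounded scalar refinement (the objective can be flat near the bounds; an
estimate at a bound is flagged). R² = 1 − SSE/SST is not clamped — negative
values are the rejection signal in the source→sink test. 95% bands are
Wilson binomial intervals (better behaved than Wald at the ~20-sample sizes
typical of biofilm studies) around the predicted frequency at n = number of
samples; taxa partition into above/within/below.

**Detection model.** When presence is defined on counts, the sharp
threshold at d ignores sampling noise: a taxon with latent abundance just
below d is detected with substantial probability and vice versa. On data
generated by the package's own neutral simulator this inflates m̂ by
20–25%. The default fit therefore predicts the probability of observing at
least one read — the Beta-binomial tail
1 − B(a, b+N_reads)/B(a, b), a = Nmp, b = Nm(1−p) — which recovers planted
m with 1–2% bias. `detection="threshold"` selects the classic Beta-tail
prediction instead (and is exact when frequencies are constructed from it).

## Pipeline and seeding

All randomness derives from one root seed split per stage by stable stage
names (CRC-32 of the name into a `SeedSequence`), so stages are independent
yet replayable and the whole run is byte-deterministic: identical resolved
config + seed reproduces identical TSV/JSON artifacts. Formats are plain
TSV (abundance, taxonomy, association matrices, edge lists, centralities),
GraphML for graphs, JSON for reports, YAML for configs. Problem sizes in
the test-suite experiments (e.g. 500 samples × 50 taxa for SparCC
calibration, 1000 taxa × 50 samples for neutral recovery, R = 500 null
replicates) were chosen as the smallest designs at which the sampling
distributions of the checked statistics are stable across seeds.

## Known limitations

* SparCC's sparsity approximation degrades when many taxa are strongly
  correlated; the iterative exclusion handles isolated strong pairs only.
* StARS instability is averaged over all pairs, so for very small taxon
  sets the criterion is coarse; selected graphs can vary across subsample
  draws (hence seed-averaged recovery reporting).
* The null-model comparison conditions on n and M only; degree-preserving
  (configuration-model) rewiring is deliberately out of scope.
* The neutral fit treats samples as exchangeable and taxa as independent
  given p; spatial or temporal autocorrelation between samples is not
  modeled.
* Edge betweenness is reported on the unweighted topology; no
  distance transform of association weights is attempted.
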