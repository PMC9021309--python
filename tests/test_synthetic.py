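import numpy as np
import pytest
from scipy import stats

from biofilmnet import (
    block_correlation,
    chain_correlation,
    clr_transform,
    correlate_features,
    simulate_compositional,
    simulate_neutral,
    simulate_paired_features,
    simulate_source_sink,
)


class TestCompositional:
    def test_counts_sum_exactly_to_depth(self):
        t, _ = simulate_compositional(20, 10, None, depth=500, seed=1)
        np.testing.assert_array_equal(t.sample_totals(), 500)
        assert np.all(t.values >= 0)
        assert np.allclose(t.values, np.round(t.values))

    def test_seeded_determinism(self):
        a, _ = simulate_compositional(15, 8, [(3, 0.5)], depth=400, seed=7)
        b, _ = simulate_compositional(15, 8, [(3, 0.5)], depth=400, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a, _ = simulate_compositional(15, 8, None, depth=400, seed=7)
        b, _ = simulate_compositional(15, 8, None, depth=400, seed=8)
        assert not np.array_equal(a.values, b.values)

    def test_non_psd_corr_rejected(self):
        bad = np.array(
            [[1, 0.9, -0.9, 0], [0.9, 1, 0.9, 0], [-0.9, 0.9, 1, 0], [0, 0, 0, 1.0]]
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_compositional(10, 4, bad, depth=200, seed=0)

    def test_depth_below_n_taxa_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            simulate_compositional(10, 20, None, depth=10, seed=0)

    def test_block_structure_visible_in_clr_spearman(self):
        # brute-force check on the generated counts: within-block rank
        # correlation of CLR values exceeds between-block
        t, _ = simulate_compositional(500, 12, [(5, 0.8)], depth=5000, seed=3)
        z = clr_transform(t, 1.0)
        rho = stats.spearmanr(z.T).statistic
        within = rho[:5, :5][np.triu_indices(5, 1)]
        between = rho[:5, 5:]
        assert within.mean() > between.mean() + 0.2

    def test_identity_clr_correlations_shrink_with_n(self):
        means = {}
        for n in (50, 500):
            t, _ = simulate_compositional(n, 10, None, depth=2000, seed=5)
            z = clr_transform(t, 1.0)
            c = np.corrcoef(z)
            means[n] = np.abs(c[np.triu_indices(10, 1)]).mean()
        assert means[500] < means[50]

    def test_truth_adjacency_block_and_chain(self):
        _, tr = simulate_compositional(10, 8, [(3, 0.6)], depth=200, seed=0)
        assert tr.planted_adjacency[:3, :3].sum() == 6  # 3 within-block pairs, sym
        assert tr.planted_adjacency[3:, :].sum() == 0
        R = chain_correlation(8, 4, 0.7)
        _, tr2 = simulate_compositional(10, 8, R, depth=200, seed=0)
        chain = tr2.planted_adjacency[:4, :4]
        assert chain.sum() == 6  # 3 consecutive pairs only
        assert chain[0, 2] == 0 and chain[0, 3] == 0

    def test_domain_labels_cover_all_taxa(self):
        t, tr = simulate_compositional(10, 12, None, depth=300, seed=0)
        assert set(tr.domain_labels) == set(t.taxon_ids)
        assert set(tr.domain_labels.values()) == {"Bacteria", "Archaea", "Eukaryota"}


class TestBlockSpec:
    def test_invalid_block_correlation_rejected(self):
        with pytest.raises(ValueError):
            block_correlation(10, [(3, 1.5)])

    def test_oversized_blocks_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            block_correlation(4, [(5, 0.5)])


class TestNeutral:
    def test_m_out_of_range_rejected(self):
        for m in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="m"):
                simulate_neutral(n_taxa=50, n_samples=10, N_reads=1000, m=m, seed=0)

    def test_sample_totals_equal_n_reads(self):
        t, _ = simulate_neutral(n_taxa=100, n_samples=10, N_reads=2000, m=0.2, seed=1)
        np.testing.assert_array_equal(t.sample_totals(), 2000)

    def test_seeded_determinism(self):
        a, _ = simulate_neutral(n_taxa=60, n_samples=8, N_reads=1000, m=0.3, seed=9)
        b, _ = simulate_neutral(n_taxa=60, n_samples=8, N_reads=1000, m=0.3, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_full_migration_abundant_taxa_always_detected(self):
        # at m = 1 a taxon with metacommunity abundance far above the
        # detection limit occurs in essentially every sample
        t, tr = simulate_neutral(n_taxa=200, n_samples=30, N_reads=100_000, m=1.0, seed=2)
        rel = t.relative().values
        p = rel.mean(axis=1)
        abundant = p > 100 / 100_000
        occ = (t.values[abundant] > 0).mean(axis=1)
        assert occ.min() > 0.99
        assert tr.true_m == 1.0


class TestSourceSink:
    def test_zero_target_samples_rejected(self):
        src, _ = simulate_neutral(n_taxa=50, n_samples=5, N_reads=1000, m=0.5, seed=0)
        with pytest.raises(ValueError, match="n_target_samples"):
            simulate_source_sink(src, m=0.3, n_target_samples=0)

    def test_taxon_set_preserved(self):
        src, _ = simulate_neutral(n_taxa=50, n_samples=5, N_reads=1000, m=0.5, seed=0)
        tgt = simulate_source_sink(src, m=0.3, n_target_samples=6, N_reads=1000, seed=1)
        assert tgt.taxon_ids == src.taxon_ids
        assert tgt.n_samples == 6


class TestPairedFeatures:
    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_paired_features(20, 5, 5, [(0, 0, 0.5), (0, 0, 0.9)], seed=0)

    def test_strength_zero_behaves_independent(self):
        a, b, _ = simulate_paired_features(200, 5, 5, [(0, 0, 0.0)], seed=3)
        rho = stats.spearmanr(a.iloc[0], b.iloc[0]).statistic
        assert abs(rho) < 0.2

    def test_planted_pair_has_high_rank_correlation(self):
        a, b, tr = simulate_paired_features(200, 5, 5, [(1, 2, 0.9)], seed=4)
        rho = stats.spearmanr(a.loc["A001"], b.loc["B002"]).statistic
        assert rho > 0.75
        assert tr.planted_pairs == [("A001", "B002", 0.9)]

    def test_determinism(self):
        a1, b1, _ = simulate_paired_features(30, 4, 4, [(0, 1, 0.5)], seed=11)
        a2, b2, _ = simulate_paired_features(30, 4, 4, [(0, 1, 0.5)], seed=11)
        assert a1.equals(a2) and b1.equals(b2)
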