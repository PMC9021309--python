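"""FDR-controlled Spearman screen between two feature tables.

Mimics correlating primary-producer abundances against enzyme-class
(e.g. CAZyme) abundances: every cross-table pair is tested, p-values are
Benjamini-Hochberg adjusted jointly, stars follow *<0.05 **<0.01 ***<0.001.
"""

import biofilmnet as bn

producers, enzymes, truth = bn.simulate_paired_features(
    n_samples=60, n_features_a=8, n_features_b=12,
    planted_pairs=[(0, 3, 0.9), (2, 7, -0.8)], seed=21,
)
report = bn.correlate_features(producers, enzymes, q=0.05)

print("planted dependencies:", truth.planted_pairs)
print(report.significant().to_string(index=False))
print(f"{len(report.significant())} of {len(report.pairs)} pairs significant at q=0.05")
# Only the planted pairs should survive the BH adjustment; rho reports the
# direction and strength of each monotone dependency.
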