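"""Unsupervised discovery of a high-methylation (CIMP-like) tumor group.

Selects the 1,000 most variable CpG loci, clusters samples by Euclidean
complete linkage, cuts the tree into three groups, and scores the partition
by average silhouette width with a permutation p-value.
"""

import cimpscan as cs

cfg = cs.SimConfig(n_probes=2500, seed=0)
signals, annotation, metadata = cs.generate_dataset(cfg)
beta = cs.compute_beta(signals)
report = cs.filter_probes(beta, signals.detection_p, metadata)

study = [s for s in beta.columns
         if metadata.loc[s, "tissue_class"] in ("normal", "tumor_low", "tumor_high")
         and metadata.loc[s, "replicate_group"] == ""]
bq = cs.drop_incomplete(beta.loc[list(report.retained)], metadata)[study]

top = cs.select_top_variable(bq, 1000)
result = cs.hcluster(bq.loc[top], 3)
print("cluster sizes:", result.group_sizes().to_dict())

sil, p = cs.silhouette_significance(bq, 3, top_k=1000, n_perm=199, seed=0)
print(f"average silhouette width = {sil:.3f}, permutation p = {p:.4f}")
# A positive silhouette with small p says the three-group structure is far
# stronger than in per-locus-shuffled data. The groups correspond to the
# normal samples plus the low- and high-methylation tumor groups.

summary = cs.group_beta_summary(bq, result.labels, annotation)
print(summary.round(3).to_string(index=False))
# mean_beta per group recovers the planted gradient; the island /
# non-island columns show the inversion: low-methylation groups are MORE
# methylated outside CpG islands, the high group inside them.
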