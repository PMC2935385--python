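"""Supervised differential methylation under the joint delta-beta/p criterion.

Compares tumors against normals: a locus passes when |delta beta| > 0.17 and
the two-sided Welch t-test gives p < 1e-4. Passing loci are collapsed to
gene symbols and the gain/loss split is tested for CpG-island-context bias.
"""

import cimpscan as cs

cfg = cs.SimConfig(n_probes=2500, seed=1)
signals, annotation, metadata = cs.generate_dataset(cfg)
beta = cs.compute_beta(signals)

normals = list(metadata.index[metadata["tissue_class"] == "normal"])
tumors = [s for s in metadata.index
          if metadata.loc[s, "tissue_class"] in ("tumor_low", "tumor_high")
          and metadata.loc[s, "replicate_group"] == ""]

res = cs.differential(beta, normals, tumors, delta_thresh=0.17, p_thresh=1e-4)
genes = res.passing_genes(annotation)
print(f"tumor vs normal: {res.n_pass} loci pass "
      f"({res.n_gain} gain / {res.n_loss} loss), {len(genes)} distinct genes")
# "gain" = hypermethylated in tumors relative to normals. Every island locus
# carries the planted group contrast (beta 0.15 in normals rising in
# tumors), so in synthetic data most of the island stratum passes.

# The high-vs-low tumor comparison shows both directions: island loci gain,
# non-island loci lose methylation in the high group.
low = [s for s in tumors if metadata.loc[s, "tissue_class"] == "tumor_low"]
high = [s for s in tumors if metadata.loc[s, "tissue_class"] == "tumor_high"]
res_hl = cs.differential(beta, low, high)
print(f"high vs low: {res_hl.n_pass} loci pass "
      f"({res_hl.n_gain} gain / {res_hl.n_loss} loss)")
table, p = cs.island_context_enrichment(res_hl, annotation)
print(table)
print(f"Fisher exact p = {p:.3g}")
# Loss-of-methylation loci concentrate outside CpG islands; the 2x2 Fisher
# test quantifies that context bias.
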