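"""Methylation-expression correlation with BH FDR, and DNMT3B group contrast.

Couples a synthetic log2 expression matrix to the beta matrix (45% of genes
inversely, 12% positively), then recovers the planted coupling directions at
FDR 0.01 and tests the DNMT3B shift between the low and high methylation
tumor groups, raw and normalized by the proliferation marker PCNA.
"""

import cimpscan as cs

cfg = cs.SimConfig(n_probes=2000, seed=3)
signals, annotation, metadata = cs.generate_dataset(cfg)
beta = cs.compute_beta(signals)
expr, probe_map = cs.generate_expression(beta, annotation, cfg, metadata=metadata)

res = cs.meth_expr_correlate(beta, expr, probe_map, fdr=0.01)
print(f"{res.n_pairs} pairs: {res.n_sig_negative} significant negative, "
      f"{res.n_sig_positive} significant positive at FDR 0.01")
print(res.gene_summary().to_dict())
t = res.table
for direction in ("negative", "positive"):
    sub = t[t["coupling"] == direction]
    ok = (sub["call"] == direction).mean()
    print(f"planted {direction} couplings recovered: {100 * ok:.1f}%")
# The dominant negative direction reflects promoter-methylation silencing:
# more methylation, less transcript.

labels = metadata.loc[expr.columns, "tissue_class"].map(
    lambda c: "high" if c == "tumor_high" else "low")
print()
print(cs.dnmt_group_compare(expr, labels).round(4).to_string(index=False))
# DNMT3B carries a planted +0.76 log2 shift in the high-methylation group;
# PCNA carries a +0.5 shift, so the PCNA-normalized contrast is attenuated —
# separating a methyltransferase signal from proliferation.
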