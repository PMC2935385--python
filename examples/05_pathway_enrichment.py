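"""Hypergeometric gene-set over-representation on a differential gene list.

Builds a small GMT collection in which one set is drawn mostly from the
differential genes, then tests every set against the array universe.
"""

import os
import tempfile

import numpy as np

import cimpscan as cs

cfg = cs.SimConfig(n_probes=2000, seed=2)
signals, annotation, metadata = cs.generate_dataset(cfg)
beta = cs.compute_beta(signals)

normals = list(metadata.index[metadata["tissue_class"] == "normal"])
tumors = [s for s in metadata.index
          if metadata.loc[s, "tissue_class"] in ("tumor_low", "tumor_high")
          and metadata.loc[s, "replicate_group"] == ""]
res = cs.differential(beta, normals, tumors)
# hit list: genes of the 60 strongest passing loci (largest |delta beta|),
# the way a focused candidate list would be drawn from a full result table
strongest = (res.table[res.table["passed"]]
             .reindex(res.table["delta_beta"].abs().sort_values(ascending=False).index)
             .dropna().head(60))
hits = sorted({s for syms in annotation.loc[strongest.index, "gene_symbol"]
               for s in str(syms).split(";")})
universe = sorted({s for syms in annotation["gene_symbol"].astype(str)
                   for s in syms.split(";")})
print(f"{len(hits)} candidate genes in a universe of {len(universe)}")

rng = np.random.default_rng(0)
enriched_set = list(rng.choice(hits, 15, replace=False)) + \
    list(rng.choice(universe, 5, replace=False))
random_set = list(rng.choice(universe, 20, replace=False))
gmt = "enriched_pathway\tplanted\t" + "\t".join(enriched_set) + "\n" \
    + "random_pathway\tnull\t" + "\t".join(random_set) + "\n"

with tempfile.TemporaryDirectory() as d:
    path = os.path.join(d, "sets.gmt")
    with open(path, "w") as fh:
        fh.write(gmt)
    sets = cs.read_gmt(path)

table = cs.hypergeom_enrich(hits, universe, sets)
print(table[["set", "k", "K", "n", "N", "p", "q"]].to_string(index=False))
# p is the upper-tail hypergeometric probability of seeing at least k of the
# set's K genes among the n hits drawn from a universe of N. The planted
# set's overlap is far beyond chance; the random set is not.
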