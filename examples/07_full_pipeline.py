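"""Run every stage end to end and print the run report.

Equivalent to `cimpscan pipeline --outdir <dir> --seed 5` with a reduced
probe count; stage tables and report.json are written to the run directory.
"""

import json
import tempfile

import cimpscan as cs

config = {
    "simulate": {"n_probes": 1500},
    "params": {"n_perm": 99},
}

with tempfile.TemporaryDirectory() as outdir:
    report = cs.run_pipeline(config, outdir, seed=5)

print(json.dumps(
    {k: report[k] for k in ("preprocess", "cluster", "diffmeth", "classify")},
    indent=2, default=str))
# preprocess: the filter ledger (detection / methylated-control / DKO) and
#   replicate concordance;
# cluster: three-group silhouette and the low/high tumor split;
# diffmeth: pass counts per comparison (tumor-vs-normal, high-vs-low,
#   IBC-vs-non-IBC) with gain/loss direction;
# classify: cross-validated shrunken-centroid classifier summary.
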