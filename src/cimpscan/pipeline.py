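"""Config-driven end-to-end run: simulate (or load) -> QC -> cluster ->
differential methylation -> classifier -> enrichment -> integration ->
clinicopathological association, writing every stage's tables plus a JSON
report to a run directory.

All stage parameters default to the analysis's standard thresholds (top-K
1,000 loci for tumor+normal clustering and 500 for tumor-only, joint
criterion delta-beta > 0.17 with p < 1e-4, 10-fold CV, FDR 0.01).  Outputs
are pure functions of (inputs, parameters, seed): the same configuration and
seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import assoc, cluster, diffmeth, enrich, integrate, preprocess, simulate
from .io import write_gene_list, write_matrix, write_table
from .nsc import nsc_cv
from .simulate import NORMAL, TUMOR_GROUPS, SimConfig

log = logging.getLogger("cimpscan")

DEFAULTS = {
    "top_k_all": 1000,       # tumor + normal clustering
    "top_k_tumor": 500,      # tumor-only clustering
    "k_all": 3,
    "k_tumor": 2,
    "delta_thresh": 0.17,
    "p_thresh": 1e-4,
    "n_perm": 199,
    "folds": 10,
    "fdr": 0.01,
}


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _sim_config(params: dict, seed: int) -> SimConfig:
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    kw = {k: v for k, v in params.items() if k in fields}
    unknown = set(params) - fields
    if unknown:
        raise ValueError(f"unknown simulator parameters: {sorted(unknown)}")
    if "expression" in kw and isinstance(kw["expression"], dict):
        kw["expression"] = simulate.ExpressionCoupling(**kw["expression"])
    kw.setdefault("seed", seed)
    return SimConfig(**kw)


def run_pipeline(config: dict, outdir: str, seed: int = 0, gmt: str | None = None) -> dict:
    """Execute every stage and return the run report (also written as JSON).

    ``config`` may carry a ``simulate`` section (SimConfig fields) and a
    ``params`` section overriding the stage defaults in ``DEFAULTS``;
    ``gmt`` optionally points to a gene-set collection for enrichment.
    """
    os.makedirs(outdir, exist_ok=True)
    params = dict(DEFAULTS)
    params.update(config.get("params", {}))
    report: dict = {"seed": seed, "params": params}

    stage = "simulate"
    try:
        sim = _sim_config(config.get("simulate", {}), seed)
        signals, annotation, meta = simulate.generate_dataset(sim)
        simulate.save_dataset(os.path.join(outdir, "data"), signals, annotation, meta)
        log.info("simulated %d probes x %d samples", *signals.M.shape)

        stage = "preprocess"
        beta = preprocess.compute_beta(signals)
        fr = preprocess.filter_probes(beta, signals.detection_p, meta)
        log.info("filters: %d detection, %d meth-control, %d DKO excluded; %d retained",
                 len(fr.excluded_detection), len(fr.excluded_meth_control),
                 len(fr.excluded_dko), len(fr.retained))
        beta_qc = preprocess.drop_incomplete(beta.loc[list(fr.retained)], meta)
        write_table(fr.summary(), os.path.join(outdir, "filter_report.tsv"),
                    index=True, index_label="category")
        write_matrix(beta_qc, os.path.join(outdir, "beta_qc.tsv"))
        # concordance over all probes: the QC'd set leaves the DKO replicate
        # with no dynamic range (its misbehaving probes are exactly the ones
        # the DKO filter removes)
        rep = preprocess.replicate_concordance(beta, meta)
        write_table(rep, os.path.join(outdir, "replicate_concordance.tsv"))
        report["preprocess"] = {
            "n_input": fr.n_input,
            "excluded_detection": len(fr.excluded_detection),
            "excluded_meth_control": len(fr.excluded_meth_control),
            "excluded_dko": len(fr.excluded_dko),
            "retained": len(fr.retained),
            "replicate_r2_mean": float(rep["r_squared"].mean()) if len(rep) else None,
        }

        study = [s for s in beta_qc.columns
                 if meta.loc[s, "tissue_class"] in TUMOR_GROUPS + (NORMAL,)
                 and meta.loc[s, "replicate_group"] == ""]
        tumors = [s for s in study if meta.loc[s, "tissue_class"] in TUMOR_GROUPS]
        normals = [s for s in study if meta.loc[s, "tissue_class"] == NORMAL]
        B = beta_qc[study]

        stage = "cluster"
        top_all = cluster.select_top_variable(B, min(params["top_k_all"], len(B)))
        res_all = cluster.hcluster(B.loc[top_all], params["k_all"])
        sil, sil_p = cluster.silhouette_significance(
            B, params["k_all"], top_k=min(params["top_k_all"], len(B)),
            n_perm=params["n_perm"], seed=seed)
        res_all.silhouette_p = sil_p
        # context summary over all retained loci (top-variance loci are
        # island-dominated on synthetic data, leaving no non-island stratum)
        summary_all = cluster.group_beta_summary(B, res_all.labels, annotation)
        write_table(res_all.labels.rename("group").to_frame(),
                    os.path.join(outdir, "cluster_all_labels.tsv"),
                    index=True, index_label="sample_id")
        write_table(pd.DataFrame(res_all.linkage, columns=["id_a", "id_b", "height", "size"]),
                    os.path.join(outdir, "cluster_all_linkage.tsv"))
        write_table(summary_all, os.path.join(outdir, "cluster_all_groups.tsv"))
        log.info("tumor+normal clustering: sizes %s, silhouette %.3f (p=%.4g)",
                 res_all.group_sizes().to_dict(), sil, sil_p)

        # tumor-only clustering defines the low/high methylation groups
        BT = B[tumors]
        top_t = cluster.select_top_variable(BT, min(params["top_k_tumor"], len(BT)))
        res_t = cluster.hcluster(BT.loc[top_t], params["k_tumor"])
        means = {g: BT.loc[top_t, res_t.labels.index[res_t.labels == g]].to_numpy().mean()
                 for g in res_t.labels.unique()}
        high_label = max(means, key=means.get)
        meth_group = res_t.labels.map(lambda g: "high" if g == high_label else "low")
        write_table(meth_group.rename("meth_group").to_frame(),
                    os.path.join(outdir, "tumor_groups.tsv"),
                    index=True, index_label="sample_id")
        report["cluster"] = {
            "k_all": params["k_all"],
            "sizes_all": {int(k): int(v) for k, v in res_all.group_sizes().items()},
            "avg_silhouette_all": res_all.avg_silhouette,
            "silhouette_p_all": sil_p,
            "avg_silhouette_tumor": res_t.avg_silhouette,
            "sizes_tumor": {str(k): int(v) for k, v in
                            meth_group.value_counts().sort_index().items()},
            "null_model": res_all.null_model,
        }

        stage = "diffmeth"
        universe = sorted({s for syms in annotation.loc[beta_qc.index, "gene_symbol"]
                           .astype(str) for s in syms.split(";") if s})
        comparisons = {}
        diff_results = {}
        pairs = {"tumor_vs_normal": (normals, tumors)}
        low = list(meth_group.index[meth_group == "low"])
        high = list(meth_group.index[meth_group == "high"])
        if len(low) >= 2 and len(high) >= 2:
            pairs["high_vs_low"] = (low, high)
        ibc = [s for s in tumors if meta.loc[s, "subtype"] == "IBC"]
        non = [s for s in tumors if meta.loc[s, "subtype"] == "nonIBC"]
        if len(ibc) >= 2 and len(non) >= 2:
            pairs["ibc_vs_nonibc"] = (non, ibc)
        for name, (ga, gb) in pairs.items():
            if len(ga) < 2 or len(gb) < 2:
                log.warning("comparison %s infeasible (group too small); skipped", name)
                continue
            res = diffmeth.differential(B, ga, gb, params["delta_thresh"], params["p_thresh"])
            genes = res.passing_genes(annotation)
            write_table(res.table, os.path.join(outdir, f"diff_{name}.tsv"),
                        index=True, index_label="probe_id")
            write_gene_list(genes, os.path.join(outdir, f"diff_{name}_genes.txt"))
            entry = {"n_pass": res.n_pass, "n_gain": res.n_gain,
                     "n_loss": res.n_loss, "n_genes": len(genes)}
            if res.n_gain and res.n_loss:
                ctx, ctx_p = diffmeth.island_context_enrichment(res, annotation)
                entry["island_context_fisher_p"] = ctx_p
            comparisons[name] = entry
            diff_results[name] = res
            log.info("%s: %d pass (%d gain / %d loss; %d genes)",
                     name, res.n_pass, res.n_gain, res.n_loss, len(genes))
        report["diffmeth"] = comparisons

        stage = "classify"
        if len(low) >= 2 and len(high) >= 2:
            feat = cluster.select_top_variable(BT, min(params["top_k_tumor"], len(BT)))
            cv = nsc_cv(BT.loc[feat], meth_group[BT.columns].to_numpy(),
                        folds=params["folds"], seed=seed)
            write_table(pd.DataFrame({"delta": cv.delta_grid, "cv_errors": cv.cv_errors,
                                      "n_features": cv.n_features}),
                        os.path.join(outdir, "nsc_cv_path.tsv"))
            write_table(cv.confusion, os.path.join(outdir, "nsc_confusion.tsv"),
                        index=True, index_label="true")
            report["classify"] = {
                "selected_delta": cv.selected_delta,
                "n_surviving_features": len(cv.model.surviving_features),
                "success_rate": cv.success_rate,
                "per_class_correct": {str(k): int(v)
                                      for k, v in cv.per_class_correct.items()},
            }
        else:
            log.warning("classification infeasible: need two tumor groups with >= 2 samples")
            report["classify"] = None

        stage = "enrich"
        if gmt and "high_vs_low" in diff_results:
            sets = enrich.read_gmt(gmt)
            hits = diff_results["high_vs_low"].passing_genes(annotation)
            er = enrich.hypergeom_enrich(hits, universe, sets)
            write_table(er, os.path.join(outdir, "enrichment.tsv"))
            report["enrich"] = {"n_sets": len(er),
                                "top_sets": er.head(5)[["set", "p"]].to_dict("records")}
        else:
            report["enrich"] = None

        stage = "integrate"
        expr, probe_map = simulate.generate_expression(beta_qc, annotation.loc[beta_qc.index],
                                                       sim, metadata=meta)
        write_matrix(expr, os.path.join(outdir, "expression.tsv"),
                     index_label="expr_probe_id")
        write_table(probe_map, os.path.join(outdir, "probe_map.tsv"))
        corr = integrate.meth_expr_correlate(beta_qc, expr, probe_map, fdr=params["fdr"])
        write_table(corr.table, os.path.join(outdir, "meth_expr_correlation.tsv"))
        gene_sum = corr.gene_summary()
        entry = {
            "n_pairs": corr.n_pairs,
            "n_sig_negative": corr.n_sig_negative,
            "n_sig_positive": corr.n_sig_positive,
            "n_genes": int(gene_sum["n_genes"]),
            "n_genes_sig": int(gene_sum["n_genes_sig"]),
        }
        if len(low) >= 2 and len(high) >= 2:
            dn = integrate.dnmt_group_compare(expr, meth_group)
            write_table(dn, os.path.join(outdir, "dnmt_comparison.tsv"))
            entry["dnmt"] = dn.to_dict("records")
        report["integrate"] = entry

        stage = "assoc"
        if len(low) >= 2 and len(high) >= 2:
            clin = diffmeth.compare_groups_clinico(meta.loc[meth_group.index], meth_group)
            write_table(clin, os.path.join(outdir, "clinico_association.tsv"))
            report["assoc"] = clin.to_dict("records")
        else:
            report["assoc"] = None
    except Exception:
        log.error("pipeline failed at stage %r; partial outputs kept in %s", stage, outdir)
        raise

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return v if np.isfinite(v) else None
    raise TypeError(f"not JSON-serializable: {type(x)}")
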