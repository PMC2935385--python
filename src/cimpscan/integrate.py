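"""Methylation-expression integration and methyltransferase group comparisons.

For every mapped (CpG probe, expression probe) pair, the Pearson correlation
between beta values and log2 expression is computed over shared samples,
with a two-sided p-value; Benjamini-Hochberg q-values are computed across
all pairs and a pair is called ``negative`` or ``positive`` (by the sign of
r) when q < fdr, else ``ns``.  A gene is counted significant when any of its
pairs is — the standard gene-level roll-up when probes are not combined
into a single statistic.

``dnmt_group_compare`` tests designated expression rows (DNMT1 / DNMT3A /
DNMT3B and the proliferation marker PCNA) between two sample groups, both
raw and normalized by the proliferation marker (log2 difference, i.e. a
ratio in linear space) — separating a methyltransferase signal from mere
proliferation differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class CorrelationResult:
    table: pd.DataFrame      # per pair: r, p, q, call
    fdr: float

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def n_sig_negative(self) -> int:
        return int((self.table["call"] == "negative").sum())

    @property
    def n_sig_positive(self) -> int:
        return int((self.table["call"] == "positive").sum())

    def gene_summary(self) -> pd.Series:
        """Counts: n_genes (in map), n_genes_sig (any significant pair)."""
        t = self.table
        sig = t.loc[t["call"] != "ns", "gene_symbol"]
        return pd.Series(
            {"n_genes": t["gene_symbol"].nunique(), "n_genes_sig": sig.nunique()}
        )


def meth_expr_correlate(beta: pd.DataFrame, expr: pd.DataFrame,
                        probe_map: pd.DataFrame, fdr: float = 0.01) -> CorrelationResult:
    """Pearson r / p / BH q per mapped pair over shared samples.

    ``probe_map`` needs columns probe_id, expr_probe_id, gene_symbol.  Pairs
    with a constant vector are reported with NaN statistics and call "ns";
    fewer than 3 shared samples overall is an error.
    """
    shared = [s for s in beta.columns if s in expr.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    B = beta[shared]
    E = expr[shared]
    r_list, p_list = [], []
    for probe, eprobe in probe_map[["probe_id", "expr_probe_id"]].itertuples(index=False):
        a = B.loc[probe].to_numpy(dtype=float)
        b = E.loc[eprobe].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
            r_list.append(np.nan)
            p_list.append(np.nan)
            continue
        res = stats.pearsonr(a[ok], b[ok])
        r_list.append(res.statistic)
        p_list.append(res.pvalue)
    table = probe_map.copy().reset_index(drop=True)
    table["r"] = r_list
    table["p"] = p_list
    q = np.full(len(table), np.nan)
    valid = np.isfinite(table["p"].to_numpy())
    if valid.any():
        q[valid] = multipletests(table["p"].to_numpy()[valid], method="fdr_bh")[1]
    table["q"] = q
    call = np.where(
        (q < fdr) & np.isfinite(q),
        np.where(table["r"].to_numpy() < 0, "negative", "positive"),
        "ns",
    )
    table["call"] = call
    return CorrelationResult(table=table, fdr=fdr)


def dnmt_group_compare(expr: pd.DataFrame, labels: pd.Series,
                       genes=("DNMT1", "DNMT3A", "DNMT3B"),
                       normalizer: str = "PCNA") -> pd.DataFrame:
    """Welch t-tests of designated expression rows between two groups.

    ``labels`` maps sample id -> group (exactly two groups); group order is
    sorted, and ``mean_low``/``mean_high`` follow that order.  For each gene
    the raw comparison and the normalizer-adjusted comparison (gene log2
    minus normalizer log2) are reported; absent genes are skipped with a
    warning.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("labels must define exactly 2 groups")
    samples = [s for s in labels.index if s in expr.columns]
    a = [s for s in samples if labels[s] == groups[0]]
    b = [s for s in samples if labels[s] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples with expression")
    norm = expr.loc[normalizer, samples] if normalizer in expr.index else None
    if normalizer and norm is None:
        warnings.warn(f"normalizer {normalizer!r} absent; normalized tests skipped")
    rows = []
    for gene in genes:
        if gene not in expr.index:
            warnings.warn(f"gene {gene!r} absent from expression matrix; skipped")
            continue
        va = expr.loc[gene, a].to_numpy(dtype=float)
        vb = expr.loc[gene, b].to_numpy(dtype=float)
        t = stats.ttest_ind(vb, va, equal_var=False)
        row = {
            "gene": gene,
            f"mean_{groups[0]}": float(va.mean()),
            f"mean_{groups[1]}": float(vb.mean()),
            "p": float(t.pvalue),
        }
        if norm is not None and gene != normalizer:
            na = (expr.loc[gene, a] - norm[a]).to_numpy(dtype=float)
            nb = (expr.loc[gene, b] - norm[b]).to_numpy(dtype=float)
            tn = stats.ttest_ind(nb, na, equal_var=False)
            row["normalized_p"] = float(tn.pvalue)
        else:
            row["normalized_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
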