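"""Supervised differential methylation under a joint delta-beta / p criterion.

A CpG locus is called differentially methylated between two sample groups
when both the effect size and the evidence clear their thresholds:
|mean beta(B) - mean beta(A)| > delta_thresh (default 0.17) and the
two-sided t-test p-value < p_thresh (default 1e-4).  No multiple-testing
correction enters the pass rule — mirroring the raw-p criterion this style
of analysis uses — but Benjamini-Hochberg q-values are reported alongside
for transparency.

Direction is "gain" when group B is hypermethylated relative to A
(delta_beta > 0), "loss" otherwise.  Passing probes are collapsed to gene
symbols, counting a probe once per distinct symbol when it maps to several.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assoc import ContingencyResult, chi_square


@dataclass
class DifferentialResult:
    """Per-probe differential methylation table + summary counts."""

    table: pd.DataFrame  # mean_a, mean_b, delta_beta, p, q, direction, passed
    group_a: tuple
    group_b: tuple
    delta_thresh: float
    p_thresh: float
    test: str  # "welch" or "pooled"

    @property
    def n_pass(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_gain(self) -> int:
        return int((self.table["passed"] & (self.table["direction"] == "gain")).sum())

    @property
    def n_loss(self) -> int:
        return int((self.table["passed"] & (self.table["direction"] == "loss")).sum())

    def passing_probes(self) -> list:
        return list(self.table.index[self.table["passed"]])

    def passing_genes(self, annotation: pd.DataFrame) -> list:
        """Distinct symbols among passing probes (multi-symbol probes count
        once per symbol); sorted."""
        symbols: set[str] = set()
        ann = annotation["gene_symbol"].astype(str)
        for probe in self.passing_probes():
            for sym in ann.loc[probe].split(";"):
                sym = sym.strip()
                if sym:
                    symbols.add(sym)
        return sorted(symbols)


def _t_test_rows(A: np.ndarray, B: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided t-test p-values with the degenerate-variance rule:
    zero variance in both groups gives p = 1 at equal means, p = 0 otherwise."""
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows are handled explicitly below; silence scipy's
        # near-identical-data precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(B, A, axis=1, equal_var=equal_var).pvalue
    var_a = A.var(axis=1, ddof=1)
    var_b = B.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    same = np.isclose(A.mean(axis=1), B.mean(axis=1))
    p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    return p


def differential(beta: pd.DataFrame, group_a, group_b,
                 delta_thresh: float = 0.17, p_thresh: float = 1e-4,
                 equal_var: bool = False) -> DifferentialResult:
    """Per-probe t-test (Welch by default) and joint-criterion pass calls.

    ``delta_beta`` is mean(B) - mean(A): positive values mean B gained
    methylation relative to A.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    A = beta[group_a].to_numpy(dtype=float)
    B = beta[group_b].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    delta = mean_b - mean_a
    p = _t_test_rows(A, B, equal_var=equal_var)
    q = multipletests(p, method="fdr_bh")[1]
    passed = (np.abs(delta) > delta_thresh) & (p < p_thresh)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "delta_beta": delta,
            "p": p,
            "q": q,
            "direction": np.where(delta > 0, "gain", "loss"),
            "passed": passed,
        },
        index=beta.index,
    )
    return DifferentialResult(
        table=table, group_a=tuple(group_a), group_b=tuple(group_b),
        delta_thresh=delta_thresh, p_thresh=p_thresh,
        test="pooled" if equal_var else "welch",
    )


def island_context_enrichment(result: DifferentialResult, annotation: pd.DataFrame):
    """Island-context composition of gain vs loss probes, with Fisher's exact p.

    Returns (2x2 DataFrame indexed (gain, loss) x (island, non_island),
    two-sided p).  p is NaN with a warning when a margin is empty.
    """
    passing = result.table[result.table["passed"]]
    if len(passing) == 0 or result.n_gain == 0 or result.n_loss == 0:
        warnings.warn("need at least one gain and one loss probe")
    isl = annotation.loc[passing.index, "in_island"].astype(bool)
    table = pd.DataFrame(
        {
            "island": [
                int((isl & (passing["direction"] == "gain")).sum()),
                int((isl & (passing["direction"] == "loss")).sum()),
            ],
            "non_island": [
                int((~isl & (passing["direction"] == "gain")).sum()),
                int((~isl & (passing["direction"] == "loss")).sum()),
            ],
        },
        index=["gain", "loss"],
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("empty margin in the context table; p undefined")
        return table, float("nan")
    p = stats.fisher_exact(table.to_numpy())[1]
    return table, float(p)


def compare_groups_clinico(meta: pd.DataFrame, labels: pd.Series,
                           features=None, correction: bool = False) -> pd.DataFrame:
    """Chi-square association of each clinicopathological feature with the
    two-group partition; one row per feature.  Features with fewer than two
    observed levels are skipped.
    """
    if labels.nunique() != 2:
        raise ValueError("labels must define exactly 2 groups")
    meta = meta.loc[labels.index]
    if features is None:
        features = [c for c in meta.columns
                    if c not in ("tissue_class", "replicate_group", "is_tumor")]
    rows = []
    for feat in features:
        vals = meta[feat].astype(str)
        keep = vals != "NA"
        tab = pd.crosstab(vals[keep], labels[keep])
        if tab.shape[0] < 2 or tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
            continue
        res: ContingencyResult = chi_square(tab.to_numpy(), correction=correction)
        rows.append({"feature": feat, "statistic": res.statistic,
                     "df": res.df, "p": res.p, "test": res.test})
    return pd.DataFrame(rows)
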