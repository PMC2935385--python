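"""Hypergeometric gene-set over-representation on gene lists.

Given a hit list (e.g. genes carrying differentially methylated loci), a
universe (all distinct symbols on the post-QC array), and a GMT collection
of gene sets, each set is tested with the upper-tail hypergeometric
probability P(X >= k) for X ~ Hypergeom(N, K, n): N = universe size,
K = set size within the universe, n = hit-list size, k = overlap.  Sets are
intersected with the universe before counting; symbols are uppercased and
deduplicated.  BH q-values are reported alongside, results sorted by p.
"""

from __future__ import annotations

import os
import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, tab-separated
    ``name <tab> description <tab> symbol...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = [p.strip() for p in line.rstrip("\n").split("\t")]
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate set name {parts[0]!r}")
            sets[parts[0]] = [s for s in parts[2:] if s]
    return sets


def _normalize(symbols) -> set[str]:
    return {str(s).upper() for s in symbols if str(s).strip()}


def hypergeom_enrich(hits, universe, sets: dict[str, list[str]]) -> pd.DataFrame:
    """Per-set over-representation table, ascending p.

    Columns: set, k (overlap), K (set size in universe), n (hits in
    universe), N (universe size), p, q, overlap_symbols.  Hits outside the
    universe are dropped with a warning and counted in ``n_hits_dropped``
    (attached as DataFrame attrs).
    """
    uni = _normalize(universe)
    if not uni:
        raise ValueError("empty universe")
    hit_set = _normalize(hits)
    dropped = hit_set - uni
    if dropped:
        warnings.warn(f"{len(dropped)} hit symbol(s) not in universe; dropped")
    hit_set &= uni
    N, n = len(uni), len(hit_set)
    rows = []
    for name, members in sets.items():
        inset = _normalize(members) & uni
        K = len(inset)
        overlap = sorted(inset & hit_set)
        k = len(overlap)
        # upper tail P(X >= k); k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, p, ";".join(overlap)))
    out = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "overlap_symbols"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
        out = out[["set", "k", "K", "n", "N", "p", "q", "overlap_symbols"]]
    out.attrs["n_hits_dropped"] = len(dropped)
    return out
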