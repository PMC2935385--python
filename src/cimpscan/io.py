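"""Delimited-table I/O shared by all stages.

Every matrix in this package travels as a tab-separated table with a header
row of sample ids and a first column of probe (or gene) ids.  Annotation,
metadata and result tables are plain TSV with a header.  These helpers exist
so that readers and writers agree on one dialect.
"""

from __future__ import annotations

import os

import pandas as pd

SEP = "\t"


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a probes x samples matrix (first column = row ids)."""
    return pd.read_csv(path, sep=SEP, index_col=0)


def write_matrix(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep=SEP, index_label=index_label, lineterminator="\n")


def read_table(path: str | os.PathLike, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, index_col=index_col)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False, index_label=None) -> None:
    df.to_csv(path, sep=SEP, index=index, index_label=index_label, lineterminator="\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_gene_list(genes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
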