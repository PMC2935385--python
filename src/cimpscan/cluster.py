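"""Variance-ranked locus selection, complete-linkage clustering and silhouettes.

Unsupervised discovery of methylation subgroups: rank CpG loci by standard
deviation across samples, keep the top K (the study used 1,000 for
tumor+normal and 500 for tumor-only), agglomerate samples with Euclidean
distance and complete linkage, cut the tree into k groups, and score the
partition by average silhouette width with a permutation p-value.

The agglomeration is implemented here (n is the number of *samples*, at most
a few hundred) so that the tie-break is fully specified: among all
minimal-distance cluster pairs, the lexicographically smallest pair of
cluster indices is merged, indices being assigned in creation order.  The
emitted linkage matrix follows the scipy convention, so scipy's dendrogram
and tree-cutting utilities apply directly.

The permutation null shuffles each locus's values across samples
independently, destroying sample-level correlation while preserving each
locus's marginal distribution; this null is a design choice of this package
(flagged in output metadata), not a published procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import silhouette_samples

PERMUTATION_NULL = "per-locus shuffle (package-defined null)"


def select_top_variable(beta: pd.DataFrame, k: int) -> list:
    """The k probes with largest sample s.d., descending; ties by probe id.

    Ties at equal s.d. are broken toward the lexicographically smaller probe
    id, which also decides inclusion at the cutoff.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(beta.index):
        raise ValueError(f"k={k} exceeds the {len(beta.index)} available probes")
    sd = beta.std(axis=1, ddof=1)
    # mergesort is stable; pre-sort by id so equal s.d. resolves lexicographically
    order = sd.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")
    return list(order.index[:k])


def complete_linkage(X: np.ndarray) -> np.ndarray:
    """Complete-linkage agglomeration of the rows of X (Euclidean distance).

    Returns a scipy-format linkage matrix.  Deterministic: ties are resolved
    toward the smallest (i, j) cluster-index pair in creation order.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff * diff).sum(axis=-1))
    np.fill_diagonal(D, np.inf)

    ids = list(range(n))        # cluster ids in creation (= position) order
    sizes = {i: 1 for i in range(n)}
    Z = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        m = D.shape[0]
        flat = np.argmin(D)     # row-major: first minimal (i, j), i < j via triu scan
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        a, b = ids[i], ids[j]
        d = D[i, j]
        Z[step] = (min(a, b), max(a, b), d, sizes[a] + sizes[b])
        # Lance-Williams complete linkage: d(new, k) = max(d(i,k), d(j,k))
        merged = np.maximum(D[i], D[j])
        keep = [p for p in range(m) if p not in (i, j)]
        D = D[np.ix_(keep, keep)]
        row = merged[keep]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = row
        D[:-1, -1] = row
        D[-1, -1] = np.inf
        ids = [ids[p] for p in keep] + [next_id]
        sizes[next_id] = sizes[a] + sizes[b]
        next_id += 1
    return Z


@dataclass
class ClusterResult:
    """A cut hierarchical clustering of samples over selected loci."""

    selected_probe_ids: list
    linkage: np.ndarray
    k: int
    labels: pd.Series          # sample_id -> group label 1..k
    avg_silhouette: float
    silhouette_p: float | None = None
    null_model: str = PERMUTATION_NULL
    group_summary: pd.DataFrame | None = None

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def average_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width under Euclidean distance; singletons score 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(np.mean(silhouette_samples(np.asarray(X, dtype=float), labels)))


def hcluster(beta_subset: pd.DataFrame, k: int) -> ClusterResult:
    """Cluster samples (columns) over the given loci and cut into k groups."""
    n_samples = beta_subset.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds {n_samples} samples")
    if k <= 0:
        raise ValueError("k must be positive")
    X = beta_subset.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("missing values in clustering input")
    Z = complete_linkage(X)
    if k == 1:
        labels = np.ones(n_samples, dtype=int)
        sil = float("nan")
    else:
        labels = fcluster(Z, t=k, criterion="maxclust")
        sil = average_silhouette(X, labels) if len(np.unique(labels)) >= 2 else float("nan")
    return ClusterResult(
        selected_probe_ids=list(beta_subset.index),
        linkage=Z,
        k=k,
        labels=pd.Series(labels, index=beta_subset.columns, name="group"),
        avg_silhouette=sil,
    )


def select_k_by_silhouette(beta_subset: pd.DataFrame, k_range=range(2, 7)) -> int:
    """Automatic group count: the k in k_range maximizing average silhouette."""
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k > beta_subset.shape[1]:
            continue
        s = hcluster(beta_subset, k).avg_silhouette
        if np.isfinite(s) and s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no feasible k in range")
    return best_k


def silhouette_significance(beta: pd.DataFrame, k: int, top_k: int | None = None,
                            n_perm: int = 999, seed: int = 0):
    """Average silhouette width of the k-group cut, with a permutation p.

    The observed statistic re-runs the full select -> cluster -> silhouette
    chain (selection only when ``top_k`` is given).  Each permutation shuffles
    every locus independently across samples and repeats the chain at the
    same k; p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if k < 2:
        raise ValueError("significance needs k >= 2")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")

    def statistic(mat: pd.DataFrame) -> float:
        sub = mat.loc[select_top_variable(mat, top_k)] if top_k else mat
        return hcluster(sub, k).avg_silhouette

    observed = statistic(beta)
    rng = np.random.default_rng(seed)
    vals = beta.to_numpy(dtype=float)
    count = 0
    for _ in range(n_perm):
        perm = np.empty_like(vals)
        for r in range(vals.shape[0]):
            perm[r] = vals[r, rng.permutation(vals.shape[1])]
        stat = statistic(pd.DataFrame(perm, index=beta.index, columns=beta.columns))
        if stat >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, p


def group_beta_summary(beta: pd.DataFrame, labels: pd.Series,
                       annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean beta, overall and by CpG-island context.

    The island-vs-non-island comparison within each group is a two-sided
    Welch t-test on the per-locus group means; NA when either context is
    absent or the test is undefined (zero variance in both contexts).
    """
    import warnings

    ann = annotation.loc[beta.index]
    isl = ann["in_island"].astype(bool).to_numpy()
    rows = []
    for g in sorted(labels.unique()):
        members = labels.index[labels == g]
        if len(members) == 0:
            warnings.warn(f"group {g} has no samples; excluded")
            continue
        locus_means = beta[list(members)].mean(axis=1).to_numpy()
        mi, mo = locus_means[isl], locus_means[~isl]
        if len(mi) == 0 or len(mo) == 0:
            p = np.nan
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                p = stats.ttest_ind(mo, mi, equal_var=False).pvalue
            if not np.isfinite(p):
                p = np.nan
        rows.append({
            "group": g,
            "n_samples": len(members),
            "mean_beta": float(np.mean(locus_means)),
            "mean_beta_island": float(np.mean(mi)) if len(mi) else np.nan,
            "mean_beta_non_island": float(np.mean(mo)) if len(mo) else np.nan,
            "context_p": p,
        })
    return pd.DataFrame(rows)
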