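"""Beta-value computation, control-anchored probe QC and reproducibility checks.

The beta value of a CpG probe is M / (M + U): the methylated-channel intensity
as a fraction of total intensity, ranging from 0 (unmethylated) to 1 (fully
methylated).  Three probe filters anchor QC to control samples:

1. detection filter — probes whose detection p-value exceeds ``p_thresh`` in
   at least ``sample_frac`` of the study (non-control) samples;
2. methylated-control filter — probes with beta below ``meth_min`` in the
   fully-methylated control (mean over controls if several);
3. DKO filter — probes with mean beta above ``dko_max`` across the
   DNMT-double-knockout (unmethylated) controls.

The filters are evaluated independently on the full probe set and combined as
a union, so the excluded sets may overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CONTROL_DKO, CONTROL_METH, SignalMatrix


class ValidationError(ValueError):
    pass


@dataclass
class FilterReport:
    """Outcome of the three-probe-filter QC step (sets of probe ids)."""

    n_input: int
    excluded_detection: frozenset
    excluded_meth_control: frozenset
    excluded_dko: frozenset
    retained: tuple  # ordered probe ids

    @property
    def excluded_union(self) -> frozenset:
        return self.excluded_detection | self.excluded_meth_control | self.excluded_dko

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [
                    self.n_input,
                    len(self.excluded_detection),
                    len(self.excluded_meth_control),
                    len(self.excluded_dko),
                    len(self.excluded_union),
                    len(self.retained),
                ]
            },
            index=[
                "input", "excluded_detection", "excluded_meth_control",
                "excluded_dko", "excluded_any", "retained",
            ],
        )


def compute_beta(signals: SignalMatrix) -> pd.DataFrame:
    """beta = M / (M + U), elementwise; NaN where the total intensity is zero.

    Scale-invariant: multiplying both channels by any positive constant leaves
    the result unchanged.
    """
    M = signals.M.to_numpy(dtype=float)
    U = signals.U.to_numpy(dtype=float)
    if (M < 0).any() or (U < 0).any():
        raise ValidationError("negative intensities")
    total = M + U
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, M / total, np.nan)
    return pd.DataFrame(beta, index=signals.M.index, columns=signals.M.columns)


def study_samples(meta: pd.DataFrame) -> list:
    """Non-control samples (normal + tumor), i.e. the cohort the filters count."""
    return [s for s, t in meta["tissue_class"].items()
            if t not in (CONTROL_METH, CONTROL_DKO)]


def filter_probes(beta: pd.DataFrame, detection_p: pd.DataFrame, meta: pd.DataFrame,
                  p_thresh: float = 0.05, sample_frac: float = 0.25,
                  meth_min: float = 0.5, dko_max: float = 0.2,
                  detection_over: str = "study") -> FilterReport:
    """Apply the three control-anchored probe filters; returns a FilterReport.

    ``detection_over`` selects which samples the detection filter counts:
    "study" (non-control cohort, the default) or "all".
    """
    for t, name in ((p_thresh, "p_thresh"), (sample_frac, "sample_frac"),
                    (meth_min, "meth_min"), (dko_max, "dko_max")):
        if not (0.0 < t < 1.0):
            raise ValidationError(f"{name} must lie in (0, 1)")
    meta = meta.loc[beta.columns]
    meth_samples = [s for s, t in meta["tissue_class"].items() if t == CONTROL_METH]
    dko_samples = [s for s, t in meta["tissue_class"].items() if t == CONTROL_DKO]
    if not meth_samples or not dko_samples:
        raise ValidationError("need at least one methylated and one DKO control sample")

    det_cols = study_samples(meta) if detection_over == "study" else list(beta.columns)
    det_frac = (detection_p[det_cols] > p_thresh).mean(axis=1)
    bad_det = det_frac >= sample_frac

    meth_mean = beta[meth_samples].mean(axis=1)
    bad_meth = meth_mean < meth_min

    dko_mean = beta[dko_samples].mean(axis=1)
    bad_dko = dko_mean > dko_max

    excluded = bad_det | bad_meth | bad_dko
    retained = tuple(beta.index[~excluded])
    return FilterReport(
        n_input=len(beta.index),
        excluded_detection=frozenset(beta.index[bad_det]),
        excluded_meth_control=frozenset(beta.index[bad_meth]),
        excluded_dko=frozenset(beta.index[bad_dko]),
        retained=retained,
    )


def drop_incomplete(beta: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Drop probes with any missing beta in a study sample (completeness contract)."""
    cols = study_samples(meta.loc[beta.columns])
    return beta.loc[beta[cols].notna().all(axis=1)]


def replicate_concordance(beta: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Squared Pearson correlation of beta per replicate pair.

    Returns one row per within-group pair with columns (replicate_group,
    sample_a, sample_b, r_squared); an empty frame (with a warning) when no
    replicate groups exist.
    """
    meta = meta.loc[beta.columns]
    rows = []
    groups = meta.loc[meta["replicate_group"].astype(str) != "", "replicate_group"]
    for gid, members in groups.groupby(groups):
        ids = list(members.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a = beta[ids[i]].to_numpy(dtype=float)
                b = beta[ids[j]].to_numpy(dtype=float)
                ok = np.isfinite(a) & np.isfinite(b)
                if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
                    warnings.warn(f"replicate pair ({ids[i]}, {ids[j]}) is constant; r undefined")
                    rows.append((gid, ids[i], ids[j], np.nan))
                    continue
                r = stats.pearsonr(a[ok], b[ok]).statistic
                rows.append((gid, ids[i], ids[j], r * r))
    if not rows:
        warnings.warn("no replicate groups of size >= 2 found")
    return pd.DataFrame(rows, columns=["replicate_group", "sample_a", "sample_b", "r_squared"])


def external_assay_correlation(beta: pd.DataFrame, external: pd.DataFrame,
                               probe_map: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Correlate array betas with an external per-gene assay (e.g. qMSP).

    ``external`` is genes x samples; ``probe_map`` pairs probe_id with a
    ``gene`` column.  One Pearson r and two-sided p per pair over shared
    samples; pairs with fewer than 3 shared samples or a constant vector are
    skipped with a warning.  ``significant`` flags p < alpha.
    """
    shared = [s for s in beta.columns if s in external.columns]
    rows = []
    for probe, gene in probe_map[["probe_id", "gene"]].itertuples(index=False):
        if probe not in beta.index or gene not in external.index:
            warnings.warn(f"pair ({probe}, {gene}) missing from input; skipped")
            continue
        a = beta.loc[probe, shared].to_numpy(dtype=float)
        b = external.loc[gene, shared].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            warnings.warn(f"pair ({probe}, {gene}) has <3 shared samples; skipped")
            continue
        if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
            warnings.warn(f"pair ({probe}, {gene}) has a constant vector; skipped")
            continue
        res = stats.pearsonr(a[ok], b[ok])
        rows.append((probe, gene, res.statistic, res.pvalue, int(ok.sum()),
                     bool(res.pvalue < alpha)))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "r", "p", "n_samples", "significant"])
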