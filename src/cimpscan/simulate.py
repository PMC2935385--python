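"""Synthetic Infinium-style methylation data with planted structure.

Emulates a two-channel 27K-style methylation array study of breast tissue:
~27,578 CpG probes (about 80% inside CpG islands) measured on normal breast
samples, a large low-methylation tumor group, a smaller high-methylation
(CIMP-like) tumor group, plus fully-methylated and DNMT double-knockout (DKO)
cell-line control samples and replicate chips.  A coupled log2 expression
matrix can be generated with configurable methylation-expression coupling
and designated DNMT1/DNMT3A/DNMT3B/PCNA rows.

The generative model:

* each probe carries a (group, island-context) mean beta; the realized beta of
  a probe in a sample is a Beta(mean * c, (1 - mean) * c) draw with
  concentration ``c`` (means of exactly 0 or 1 are kept degenerate so the
  noise-free limits are exact);
* methylated / unmethylated channel intensities are ``scale * beta`` and
  ``scale * (1 - beta)`` times independent log-normal multiplicative noise
  (unit mean);
* detection p-values are near zero except for Bernoulli-masked failures,
  drawn uniformly on (0.05, 1]; a small set of "bad" probes fails in about
  half the samples, mimicking probes a detection filter should remove;
* designated probe subsets misbehave in the control samples (low beta in the
  methylated control, high beta in the DKO control) so that control-anchored
  QC filters have planted targets;
* replicate samples share the true beta of their origin sample and differ
  only in intensity noise.

One integer seed drives a single numpy Generator; identical configuration and
seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import write_matrix, write_table

NORMAL = "normal"
TUMOR_LOW = "tumor_low"
TUMOR_HIGH = "tumor_high"
CONTROL_METH = "control_meth"
CONTROL_DKO = "control_dko"

TUMOR_GROUPS = (TUMOR_LOW, TUMOR_HIGH)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SignalMatrix:
    """Raw two-channel array layer: probes x samples intensities + detection p."""

    M: pd.DataFrame
    U: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.M.shape == self.U.shape == self.detection_p.shape):
            raise ValueError("M, U and detection_p must share dimensions")
        if (self.M.values < 0).any() or (self.U.values < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def probe_ids(self) -> pd.Index:
        return self.M.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.M.columns


@dataclass
class ExpressionCoupling:
    """Methylation-expression coupling plan for the synthetic expression layer.

    ``fraction_negative`` of genes get log2 expression
    ``intercept - slope * beta + noise`` (the canonical silencing direction),
    ``fraction_positive`` get ``+ slope * beta``, the rest are independent
    noise around the intercept.
    """

    fraction_negative: float = 0.45
    fraction_positive: float = 0.12
    slope_negative: float = 3.0
    slope_positive: float = 3.0
    intercept: float = 8.0
    noise_sd: float = 0.5


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults are the emulated study's conditions: 10 normals, 49 low-beta and
    13 high-beta tumors, one methylated and two DKO control samples, three
    replicate pairs, ~80% island probes, and (island, non-island) group mean
    betas of (0.15, 0.65) / (0.33, 0.58) / (0.54, 0.44) for normal / low /
    high — giving overall means 0.25, 0.38 and 0.52 and the inverted
    island-context pattern in which low-methylation groups are more methylated
    *outside* islands while the high group is more methylated inside them.
    """

    n_probes: int = 27578
    island_fraction: float = 0.8
    n_normal: int = 10
    n_tumor_low: int = 49
    n_tumor_high: int = 13
    n_control_meth: int = 1
    n_control_dko: int = 2
    n_replicate_pairs: int = 3
    # (island, non-island) mean beta per tissue group
    group_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            NORMAL: (0.15, 0.65),
            TUMOR_LOW: (0.33, 0.58),
            TUMOR_HIGH: (0.54, 0.44),
        }
    )
    beta_concentration: float = 50.0
    intensity_scale: float = 2000.0
    intensity_noise_sd: float = 0.035  # calibrated to replicate r^2 ~ 0.97
    # detection failures: low background rate everywhere, plus a small set of
    # bad probes failing in about half the samples
    detection_failure_rate: float = 0.0005
    frac_probes_bad_detection: float = 68 / 27578
    bad_probe_failure_rate: float = 0.5
    # probes that misbehave in control samples (QC-filter targets)
    frac_probes_meth_fail: float = 28 / 27578
    frac_probes_dko_fail: float = 4067 / 27578
    # tumor subtype labels
    ibc_fraction_high: float = 0.54
    ibc_fraction_low: float = 0.24
    n_ibc_effect_loci: int = 4
    ibc_effect_delta: float = 0.2
    # optional focal differential planting: loci where the high group's mean
    # is shifted by diff_delta relative to the low group's
    n_diff_loci: int = 0
    diff_delta: float = 0.0
    n_genes: int | None = None  # default: ceil(n_probes / 2)
    multi_symbol_fraction: float = 0.01
    expression: ExpressionCoupling = field(default_factory=ExpressionCoupling)
    # designated expression rows: symbol -> (low-group mean, high-group shift)
    dnmt_expression: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "DNMT3B": (5.76, 0.76),
            "DNMT1": (6.0, 0.4),
            "DNMT3A": (6.0, 0.0),
            "PCNA": (7.0, 0.5),
        }
    )
    dnmt_noise_sd: float = 0.8
    # planted clinicopathological structure: feature -> (positive level,
    # negative level, P(positive | high group), P(positive | low group))
    clinico: dict[str, tuple[str, str, float, float]] = field(
        default_factory=lambda: {
            "M_status": ("positive", "negative", 0.46, 0.10),
            "prognosis": ("poor", "good", 0.77, 0.45),
            "genomic_grade": ("high", "low", 0.67, 0.38),
            "ER": ("positive", "negative", 0.68, 0.68),
            "PR": ("positive", "negative", 0.44, 0.44),
            "HER2": ("positive", "negative", 0.32, 0.32),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_probes, self.n_normal, self.n_tumor_low, self.n_tumor_high,
            self.n_control_meth, self.n_control_dko, self.n_replicate_pairs,
            self.n_ibc_effect_loci, self.n_diff_loci,
        ]
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        props = [
            self.island_fraction, self.detection_failure_rate,
            self.frac_probes_bad_detection, self.bad_probe_failure_rate,
            self.frac_probes_meth_fail, self.frac_probes_dko_fail,
            self.ibc_fraction_high, self.ibc_fraction_low,
            self.multi_symbol_fraction,
            self.expression.fraction_negative, self.expression.fraction_positive,
        ]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ConfigurationError("proportions must lie in [0, 1]")
        if self.expression.fraction_negative + self.expression.fraction_positive > 1:
            raise ConfigurationError("expression coupling fractions must sum to <= 1")
        if self.beta_concentration <= 0 or self.intensity_scale <= 0:
            raise ConfigurationError("dispersion and intensity scale must be positive")
        for g, (isl, non) in self.group_means.items():
            if not (0.0 <= isl <= 1.0 and 0.0 <= non <= 1.0):
                raise ConfigurationError(f"group means for {g!r} must lie in [0, 1]")
        # planted CIMP contrast: island-context hypermethylation must be orderable
        if TUMOR_LOW in self.group_means and TUMOR_HIGH in self.group_means:
            if not self.group_means[TUMOR_LOW][0] <= self.group_means[TUMOR_HIGH][0]:
                raise ConfigurationError(
                    "island-context mean of tumor_low must not exceed tumor_high"
                )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _draw_beta(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    """Beta draw with the configured mean; means of exactly 0/1 stay exact."""
    mean = np.asarray(mean, dtype=float)
    out = np.empty_like(mean)
    interior = (mean > 0.0) & (mean < 1.0)
    if interior.any():
        m = mean[interior]
        out[interior] = rng.beta(m * conc, (1.0 - m) * conc)
    out[mean <= 0.0] = 0.0
    out[mean >= 1.0] = 1.0
    return out


def _noise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal factor; exactly 1 when sd == 0."""
    if sd == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sd, size=shape) - sd * sd / 2.0)


def generate_dataset(config: SimConfig):
    """Generate (SignalMatrix, ProbeAnnotation, SampleMetadata).

    Annotation is a DataFrame indexed by probe_id with columns ``gene_symbol``
    (possibly ';'-separated), ``in_island``, and planted-truth columns
    ``true_dko_fail``, ``true_meth_fail``, ``true_bad_detection``,
    ``true_diff`` and ``true_ibc_locus`` for recovery tests.  Metadata is a
    DataFrame indexed by sample_id with ``tissue_class``, ``subtype``,
    ``replicate_group`` and clinicopathological columns.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_probes

    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    in_island = np.zeros(n, dtype=bool)
    n_island = int(round(n * config.island_fraction))
    in_island[rng.permutation(n)[:n_island]] = True

    n_genes = config.n_genes if config.n_genes is not None else -(-n // 2)
    n_genes = max(1, min(n_genes, n))
    gene_of_probe = rng.integers(0, n_genes, size=n)
    symbols = np.array([f"GENE{g + 1:05d}" for g in gene_of_probe], dtype=object)
    multi = rng.random(n) < config.multi_symbol_fraction
    extra = rng.integers(0, n_genes, size=n)
    for i in np.flatnonzero(multi):
        if extra[i] != gene_of_probe[i]:
            symbols[i] = f"{symbols[i]};GENE{extra[i] + 1:05d}"

    # disjoint planted probe subsets
    perm = rng.permutation(n)
    k_bad = int(round(n * config.frac_probes_bad_detection))
    k_meth = int(round(n * config.frac_probes_meth_fail))
    k_dko = int(round(n * config.frac_probes_dko_fail))
    bad_det = perm[:k_bad]
    meth_fail = perm[k_bad:k_bad + k_meth]
    dko_fail = perm[k_bad + k_meth:k_bad + k_meth + k_dko]
    rest = perm[k_bad + k_meth + k_dko:]
    diff_loci = rest[:config.n_diff_loci]
    ibc_loci = rest[config.n_diff_loci:config.n_diff_loci + config.n_ibc_effect_loci]

    groups = (
        [(NORMAL, config.n_normal, "N")]
        + [(TUMOR_LOW, config.n_tumor_low, "TL")]
        + [(TUMOR_HIGH, config.n_tumor_high, "TH")]
        + [(CONTROL_METH, config.n_control_meth, "CM")]
        + [(CONTROL_DKO, config.n_control_dko, "DKO")]
    )
    sample_ids: list[str] = []
    tissue: list[str] = []
    for gname, count, prefix in groups:
        for j in range(count):
            sample_ids.append(f"{prefix}{j + 1:02d}")
            tissue.append(gname)
    tissue_arr = np.array(tissue, dtype=object)

    # per-probe, per-group mean beta
    mean_by_group: dict[str, np.ndarray] = {}
    for gname in (NORMAL, TUMOR_LOW, TUMOR_HIGH):
        isl, non = config.group_means.get(gname, (0.5, 0.5))
        mean_by_group[gname] = np.where(in_island, isl, non).astype(float)
    if config.n_diff_loci:
        shifted = mean_by_group[TUMOR_HIGH].copy()
        shifted[diff_loci] = np.clip(
            mean_by_group[TUMOR_LOW][diff_loci] + config.diff_delta, 0.0, 1.0
        )
        mean_by_group[TUMOR_HIGH] = shifted
    mean_by_group[CONTROL_METH] = np.ones(n)
    mean_by_group[CONTROL_DKO] = np.zeros(n)
    # control-misbehaving probes
    mean_by_group[CONTROL_METH] = mean_by_group[CONTROL_METH].copy()
    mean_by_group[CONTROL_METH][meth_fail] = 0.2
    mean_by_group[CONTROL_DKO] = mean_by_group[CONTROL_DKO].copy()
    mean_by_group[CONTROL_DKO][dko_fail] = 0.6

    # subtype labels for tumors
    subtype = np.array(["NA"] * len(sample_ids), dtype=object)
    for gname, frac in ((TUMOR_LOW, config.ibc_fraction_low), (TUMOR_HIGH, config.ibc_fraction_high)):
        idx = np.flatnonzero(tissue_arr == gname)
        subtype[idx] = np.where(rng.random(len(idx)) < frac, "IBC", "nonIBC")

    # true beta per probe x sample
    true_beta = np.empty((n, len(sample_ids)))
    for j, gname in enumerate(tissue):
        true_beta[:, j] = _draw_beta(rng, mean_by_group[gname], config.beta_concentration)
    if config.n_ibc_effect_loci:
        ibc_cols = np.flatnonzero(subtype == "IBC")
        for j in ibc_cols:
            true_beta[ibc_loci, j] = np.clip(
                true_beta[ibc_loci, j] + config.ibc_effect_delta, 0.0, 1.0
            )

    # replicate samples: copy true beta, fresh noise
    replicate_group = np.array([""] * len(sample_ids), dtype=object)
    rep_candidates = [
        i for i, t in enumerate(tissue)
        if t in (TUMOR_LOW, TUMOR_HIGH, CONTROL_DKO)
    ]
    # the study's layout: two tumors and one DKO per triple of pairs —
    # round-robin over the tumor/DKO groups, advancing within each group
    by_group = {t: [i for i, tt in enumerate(tissue) if tt == t]
                for t in (TUMOR_LOW, TUMOR_HIGH, CONTROL_DKO)}
    rotation = [t for t in (TUMOR_LOW, TUMOR_HIGH, CONTROL_DKO) if by_group[t]]
    origins: list[int] = []
    taken = {t: 0 for t in rotation}
    r = 0
    while rotation and len(origins) < config.n_replicate_pairs:
        t = rotation[r % len(rotation)]
        members = by_group[t]
        origins.append(members[taken[t] % len(members)])
        taken[t] += 1
        r += 1
    rep_cols = []
    for r, oi in enumerate(origins):
        rid = f"{sample_ids[oi]}_rep"
        sample_ids.append(rid)
        tissue.append(tissue[oi])
        subtype = np.append(subtype, subtype[oi])
        replicate_group = np.append(replicate_group, f"rep{r + 1}")
        replicate_group[oi] = f"rep{r + 1}"
        rep_cols.append(oi)
    if rep_cols:
        true_beta = np.hstack([true_beta, true_beta[:, rep_cols]])

    n_samples = len(sample_ids)
    scale = config.intensity_scale
    M = scale * true_beta * _noise(rng, config.intensity_noise_sd, (n, n_samples))
    U = scale * (1.0 - true_beta) * _noise(rng, config.intensity_noise_sd, (n, n_samples))

    det = rng.uniform(0.0, 0.01, size=(n, n_samples))
    fail_rate = np.full(n, config.detection_failure_rate)
    fail_rate[bad_det] = config.bad_probe_failure_rate
    fail_mask = rng.random((n, n_samples)) < fail_rate[:, None]
    det[fail_mask] = rng.uniform(0.05, 1.0, size=int(fail_mask.sum()))
    # uniform on (0.05, 1]: flip the half-open end
    det[fail_mask] = 1.05 - det[fail_mask]

    cols = pd.Index(sample_ids, name="sample_id")
    rows = pd.Index(probe_ids, name="probe_id")
    signals = SignalMatrix(
        M=pd.DataFrame(M, index=rows, columns=cols),
        U=pd.DataFrame(U, index=rows, columns=cols),
        detection_p=pd.DataFrame(det, index=rows, columns=cols),
    )

    annotation = pd.DataFrame(
        {
            "gene_symbol": symbols,
            "in_island": in_island,
            "true_bad_detection": np.isin(np.arange(n), bad_det),
            "true_meth_fail": np.isin(np.arange(n), meth_fail),
            "true_dko_fail": np.isin(np.arange(n), dko_fail),
            "true_diff": np.isin(np.arange(n), diff_loci),
            "true_ibc_locus": np.isin(np.arange(n), ibc_loci),
        },
        index=rows,
    )

    tissue_arr = np.array(tissue, dtype=object)
    meta = pd.DataFrame(
        {
            "tissue_class": tissue_arr,
            "subtype": subtype,
            "replicate_group": replicate_group,
        },
        index=cols,
    )
    # clinicopathological features for tumor samples; planted enrichment in the
    # high-beta group, neutral features identically distributed
    is_tumor = np.isin(tissue_arr, TUMOR_GROUPS)
    for feat, (pos, neg, p_high, p_low) in config.clinico.items():
        vals = np.array(["NA"] * n_samples, dtype=object)
        for gname, p in ((TUMOR_LOW, p_low), (TUMOR_HIGH, p_high)):
            idx = np.flatnonzero(tissue_arr == gname)
            vals[idx] = np.where(rng.random(len(idx)) < p, pos, neg)
        meta[feat] = vals
    meta["is_tumor"] = is_tumor
    return signals, annotation, meta


def generate_expression(beta: pd.DataFrame, annotation: pd.DataFrame,
                        config: SimConfig, metadata: pd.DataFrame | None = None):
    """Generate (ExpressionMatrix, ProbeGeneMap) coupled to a beta matrix.

    One expression probe per gene, paired with one representative CpG probe.
    If ``metadata`` is given, expression covers tumor samples only and the
    designated DNMT/PCNA rows receive their configured high-group shift;
    otherwise all samples are used and no shift is applied.

    The map carries a ``coupling`` column in {negative, positive, none} as
    planted ground truth.
    """
    if not beta.index.equals(annotation.index):
        raise ValueError("beta and annotation probe ids are not aligned")
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    cp = config.expression

    if metadata is not None:
        samples = [s for s in beta.columns
                   if metadata.loc[s, "tissue_class"] in TUMOR_GROUPS
                   and metadata.loc[s, "replicate_group"] == ""]
        high = {s for s in samples if metadata.loc[s, "tissue_class"] == TUMOR_HIGH}
    else:
        samples = list(beta.columns)
        high = set()
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to couple expression")
    B = beta[samples]

    # first probe of each gene (first symbol only) is its representative
    first_symbol = annotation["gene_symbol"].astype(str).str.split(";").str[0]
    rep = first_symbol.groupby(first_symbol).apply(lambda s: s.index[0])
    genes = np.array(sorted(rep.index))
    rng.shuffle(genes)
    n_g = len(genes)
    n_neg = int(round(cp.fraction_negative * n_g))
    n_pos = int(round(cp.fraction_positive * n_g))
    coupling = np.array(["none"] * n_g, dtype=object)
    coupling[:n_neg] = "negative"
    coupling[n_neg:n_neg + n_pos] = "positive"

    rows = []
    values = np.empty((n_g, len(samples)))
    for gi, gene in enumerate(genes):
        b = B.loc[rep[gene]].to_numpy(dtype=float)
        noise = rng.normal(0.0, cp.noise_sd, size=len(samples))
        if coupling[gi] == "negative":
            v = cp.intercept - cp.slope_negative * b + noise
        elif coupling[gi] == "positive":
            v = cp.intercept + cp.slope_positive * b + noise
        else:
            v = cp.intercept + noise
        values[gi] = v
        rows.append((rep[gene], f"ps_{gene}", gene, coupling[gi]))

    expr = pd.DataFrame(values, index=pd.Index([f"ps_{g}" for g in genes], name="expr_probe_id"),
                        columns=pd.Index(samples, name="sample_id"))
    # designated methyltransferase / proliferation rows
    hi_mask = np.array([s in high for s in samples])
    for sym, (base, shift) in config.dnmt_expression.items():
        v = base + rng.normal(0.0, config.dnmt_noise_sd, size=len(samples))
        v = v + shift * hi_mask
        expr.loc[sym] = v

    probe_map = pd.DataFrame(rows, columns=["probe_id", "expr_probe_id", "gene_symbol", "coupling"])
    probe_map = probe_map.sort_values("probe_id", kind="mergesort").reset_index(drop=True)
    return expr, probe_map


def save_dataset(outdir: str | os.PathLike, signals: SignalMatrix,
                 annotation: pd.DataFrame, metadata: pd.DataFrame) -> None:
    """Write the standard delimited tables for a generated dataset."""
    os.makedirs(outdir, exist_ok=True)
    write_matrix(signals.M, os.path.join(outdir, "signal_M.tsv"))
    write_matrix(signals.U, os.path.join(outdir, "signal_U.tsv"))
    write_matrix(signals.detection_p, os.path.join(outdir, "detection_p.tsv"))
    write_table(annotation, os.path.join(outdir, "annotation.tsv"), index=True, index_label="probe_id")
    write_table(metadata, os.path.join(outdir, "metadata.tsv"), index=True, index_label="sample_id")


def load_dataset(indir: str | os.PathLike):
    from .io import read_matrix, read_table

    signals = SignalMatrix(
        M=read_matrix(os.path.join(indir, "signal_M.tsv")),
        U=read_matrix(os.path.join(indir, "signal_U.tsv")),
        detection_p=read_matrix(os.path.join(indir, "detection_p.tsv")),
    )
    annotation = read_table(os.path.join(indir, "annotation.tsv"), index_col="probe_id")
    metadata = read_table(os.path.join(indir, "metadata.tsv"), index_col="sample_id")
    metadata["replicate_group"] = metadata["replicate_group"].fillna("")
    return signals, annotation, metadata
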