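"""Generator correctness: determinism, planted structure, noise model limits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cimpscan import (
    ExpressionCoupling,
    SimConfig,
    compute_beta,
    generate_dataset,
    generate_expression,
)
from cimpscan.simulate import ConfigurationError

from conftest import clean_config, flat_means


def test_seed_determinism_bit_identical():
    cfg = SimConfig(n_probes=300, seed=42)
    a = generate_dataset(cfg)
    b = generate_dataset(cfg)
    for x, y in ((a[0].M, b[0].M), (a[0].U, b[0].U), (a[0].detection_p, b[0].detection_p)):
        pd.testing.assert_frame_equal(x, y)
    pd.testing.assert_frame_equal(a[1], b[1])
    pd.testing.assert_frame_equal(a[2], b[2])


def test_different_seed_differs():
    a = generate_dataset(SimConfig(n_probes=100, seed=1))
    b = generate_dataset(SimConfig(n_probes=100, seed=2))
    assert not np.allclose(a[0].M.values, b[0].M.values)


def test_noise_free_fully_methylated_island_limit():
    """Zero noise + island mean 1.0 gives beta exactly 1.0 at island probes."""
    cfg = clean_config(
        n_probes=50, n_normal=0, n_tumor_low=0, n_tumor_high=1,
        n_control_meth=0, n_control_dko=0,
        group_means={"normal": (0.5, 0.5), "tumor_low": (0.5, 0.5),
                     "tumor_high": (1.0, 0.3)},
        intensity_noise_sd=0.0, seed=3,
    )
    signals, ann, meta = generate_dataset(cfg)
    beta = compute_beta(signals)
    island = ann.index[ann["in_island"]]
    assert (beta.loc[island].values == 1.0).all()


def test_group_means_within_three_standard_errors():
    """Empirical (group, context) mean beta matches the configured mean.

    The standard-error bound comes straight from the Beta-draw variance
    m(1-m)/(c+1), independent of the generator's sampling path.
    """
    cfg = clean_config(n_probes=2000, intensity_noise_sd=0.0, seed=9)
    signals, ann, meta = generate_dataset(cfg)
    beta = compute_beta(signals)
    c = cfg.beta_concentration
    for group, (mi, mo) in cfg.group_means.items():
        cols = meta.index[meta["tissue_class"] == group]
        for ctx_mean, mask in ((mi, ann["in_island"]), (mo, ~ann["in_island"])):
            vals = beta.loc[ann.index[mask], cols].to_numpy()
            se = np.sqrt(ctx_mean * (1 - ctx_mean) / (c + 1) / vals.size)
            assert abs(vals.mean() - ctx_mean) < 3 * se


def test_control_sample_means():
    """Controls are clean references on the reliable (non-planted) probes:
    fully-methylated control near beta 1, DKO near 0.  (Planted QC-failure
    probes misbehave by design and are what the filters remove.)"""
    cfg = SimConfig(n_probes=1000, seed=4)
    signals, ann, meta = generate_dataset(cfg)
    beta = compute_beta(signals)
    cm = meta.index[meta["tissue_class"] == "control_meth"]
    dko = meta.index[meta["tissue_class"] == "control_dko"]
    clean = ann.index[~(ann["true_meth_fail"] | ann["true_dko_fail"])]
    assert beta.loc[clean, cm].values.mean() > 0.95
    assert beta.loc[clean, dko].values.mean() < 0.05


def test_group_ordering_and_island_inversion():
    """Noise-free means respect high > low per context when so configured,
    and the default configuration reproduces the island-context inversion
    (low-mean groups more methylated outside islands, high group inside)."""
    ordered = clean_config(
        n_probes=800, intensity_noise_sd=0.0, seed=5,
        group_means={"normal": (0.1, 0.2), "tumor_low": (0.3, 0.4),
                     "tumor_high": (0.6, 0.7)},
    )
    signals, ann, meta = generate_dataset(ordered)
    beta = compute_beta(signals)

    def ctx_mean(group, island):
        cols = meta.index[meta["tissue_class"] == group]
        mask = ann["in_island"] if island else ~ann["in_island"]
        return beta.loc[ann.index[mask], cols].values.mean()

    for island in (True, False):
        assert ctx_mean("tumor_high", island) > ctx_mean("tumor_low", island)

    default = clean_config(n_probes=800, intensity_noise_sd=0.0, seed=6)
    signals, ann, meta = generate_dataset(default)
    beta = compute_beta(signals)
    for group in ("normal", "tumor_low"):
        assert ctx_mean(group, False) > ctx_mean(group, True)
    assert ctx_mean("tumor_high", True) > ctx_mean("tumor_high", False)


def test_replicates_share_truth_and_differ_by_noise():
    cfg = SimConfig(n_probes=500, n_replicate_pairs=2, seed=7)
    signals, ann, meta = generate_dataset(cfg)
    reps = meta[meta["replicate_group"] != ""]
    assert reps["replicate_group"].value_counts().eq(2).all()
    for gid, members in reps.groupby("replicate_group"):
        a, b = members.index
        assert not np.allclose(signals.M[a], signals.M[b])  # noise differs
        assert members["tissue_class"].nunique() == 1


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(island_fraction=1.5).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(n_probes=-1).validate()
    with pytest.raises(ConfigurationError):
        SimConfig(beta_concentration=0.0).validate()
    with pytest.raises(ConfigurationError):
        # planted CIMP contrast must be orderable on the island context
        SimConfig(group_means={"normal": (0.1, 0.6), "tumor_low": (0.6, 0.5),
                               "tumor_high": (0.3, 0.5)}).validate()


class TestExpression:
    def test_exact_inverse_coupling_noise_free(self):
        cfg = clean_config(
            n_probes=60, seed=8,
            expression=ExpressionCoupling(fraction_negative=1.0, fraction_positive=0.0,
                                          slope_negative=1.0, noise_sd=0.0),
        )
        signals, ann, meta = generate_dataset(cfg)
        beta = compute_beta(signals)
        expr, pmap = generate_expression(beta, ann, cfg, metadata=meta)
        samples = list(expr.columns)
        for probe, eprobe, _, coupling in pmap.itertuples(index=False):
            assert coupling == "negative"
            r = stats.pearsonr(beta.loc[probe, samples], expr.loc[eprobe, samples]).statistic
            assert r == pytest.approx(-1.0)

    def test_null_coupling_calibrated(self):
        """With no coupling, the fraction of |r| exceeding the alpha critical
        value is approximately alpha (Monte-Carlo calibration, ~2,000 pairs)."""
        cfg = clean_config(
            n_probes=4000, n_genes=2000, seed=10,
            expression=ExpressionCoupling(fraction_negative=0.0, fraction_positive=0.0),
        )
        signals, ann, meta = generate_dataset(cfg)
        beta = compute_beta(signals)
        expr, pmap = generate_expression(beta, ann, cfg, metadata=meta)
        samples = list(expr.columns)
        alpha = 0.05
        hits = 0
        for probe, eprobe in pmap[["probe_id", "expr_probe_id"]].itertuples(index=False):
            p = stats.pearsonr(beta.loc[probe, samples], expr.loc[eprobe, samples]).pvalue
            hits += p < alpha
        frac = hits / len(pmap)
        # binomial 3-sigma band around alpha
        band = 3 * np.sqrt(alpha * (1 - alpha) / len(pmap))
        assert abs(frac - alpha) < band + 0.005

    def test_dnmt3b_planted_shift_recovered(self):
        """A +0.76 log2 shift for the high group is recovered (p < 0.05) in
        most cohorts at group sizes (49, 13); power checked by simulation."""
        sig_count = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = clean_config(n_probes=40, seed=100 + rep)
            signals, ann, meta = generate_dataset(cfg)
            beta = compute_beta(signals)
            expr, _ = generate_expression(beta, ann, cfg, metadata=meta)
            high = [s for s in expr.columns if meta.loc[s, "tissue_class"] == "tumor_high"]
            low = [s for s in expr.columns if meta.loc[s, "tissue_class"] == "tumor_low"]
            res = stats.ttest_ind(expr.loc["DNMT3B", high], expr.loc["DNMT3B", low],
                                  equal_var=False)
            shift = expr.loc["DNMT3B", high].mean() - expr.loc["DNMT3B", low].mean()
            if res.pvalue < 0.05 and shift > 0:
                sig_count += 1
        # analytic power at d = 0.76 / 0.8-ish sd and n = (49, 13) is ~0.8
        assert sig_count >= 12

    def test_misaligned_annotation_raises(self):
        cfg = clean_config(n_probes=30, seed=11)
        signals, ann, meta = generate_dataset(cfg)
        beta = compute_beta(signals)
        with pytest.raises(ValueError):
            generate_expression(beta.iloc[:-2], ann, cfg, metadata=meta)
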