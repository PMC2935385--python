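"""Beta computation, probe filters (with brute-force oracle) and concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cimpscan import (
    SignalMatrix,
    SimConfig,
    compute_beta,
    external_assay_correlation,
    filter_probes,
    generate_dataset,
    replicate_concordance,
)
from cimpscan.preprocess import ValidationError

from conftest import beta_frame


def make_signals(M, U, det=None):
    M = np.atleast_2d(np.asarray(M, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if det is None:
        det = np.zeros_like(M)
    probes = pd.Index([f"cg{i:04d}" for i in range(M.shape[0])], name="probe_id")
    samples = pd.Index([f"S{j:02d}" for j in range(M.shape[1])], name="sample_id")
    return SignalMatrix(
        M=pd.DataFrame(M, index=probes, columns=samples),
        U=pd.DataFrame(U, index=probes, columns=samples),
        detection_p=pd.DataFrame(np.atleast_2d(det), index=probes, columns=samples),
    )


class TestComputeBeta:
    @pytest.mark.parametrize("m,u,expected", [(100, 0, 1.0), (0, 100, 0.0), (50, 150, 0.25)])
    def test_printed_formula_values(self, m, u, expected):
        beta = compute_beta(make_signals([[m]], [[u]]))
        assert beta.iloc[0, 0] == pytest.approx(expected)

    def test_zero_total_is_missing(self):
        beta = compute_beta(make_signals([[0.0]], [[0.0]]))
        assert np.isnan(beta.iloc[0, 0])

    def test_negative_intensity_rejected(self):
        sig = make_signals([[1.0]], [[1.0]])
        sig.M.iloc[0, 0] = -1.0
        with pytest.raises(ValidationError):
            compute_beta(sig)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6),
           st.integers(min_value=0, max_value=10**6))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(0, 1000, (5, 4))
        U = rng.uniform(0, 1000, (5, 4))
        b1 = compute_beta(make_signals(M, U))
        b2 = compute_beta(make_signals(c * M, c * U))
        np.testing.assert_allclose(b1.values, b2.values, rtol=1e-9)


def filter_oracle(beta, det, meta, p_thresh=0.05, sample_frac=0.25,
                  meth_min=0.5, dko_max=0.2):
    """Independent per-probe rule evaluation (pure python loops)."""
    study = [s for s in beta.columns
             if meta.loc[s, "tissue_class"] not in ("control_meth", "control_dko")]
    cm = [s for s in beta.columns if meta.loc[s, "tissue_class"] == "control_meth"]
    dk = [s for s in beta.columns if meta.loc[s, "tissue_class"] == "control_dko"]
    out = {"det": set(), "meth": set(), "dko": set()}
    for p in beta.index:
        n_fail = sum(det.loc[p, s] > p_thresh for s in study)
        if n_fail >= sample_frac * len(study):
            out["det"].add(p)
        if np.mean([beta.loc[p, s] for s in cm]) < meth_min:
            out["meth"].add(p)
        if np.mean([beta.loc[p, s] for s in dk]) > dko_max:
            out["dko"].add(p)
    return out


def small_cohort_meta(n_study, n_cm=1, n_dko=2):
    ids = [f"S{j:02d}" for j in range(n_study + n_cm + n_dko)]
    tissue = ["tumor_low"] * n_study + ["control_meth"] * n_cm + ["control_dko"] * n_dko
    return pd.DataFrame({"tissue_class": tissue, "replicate_group": ""},
                        index=pd.Index(ids, name="sample_id"))


class TestFilterProbes:
    def test_no_violations_keeps_everything(self):
        beta = beta_frame(np.full((8, 7), 0.6))
        beta.iloc[:, 5:7] = 0.05  # DKO control columns stay unmethylated
        det = beta_frame(np.zeros((8, 7)))
        meta = small_cohort_meta(4)
        rep = filter_probes(beta, det, meta)
        assert set(rep.retained) == set(beta.index)
        assert rep.excluded_union == frozenset()

    def test_ten_probe_fixture_matches_rule_evaluation(self):
        """2 probes fail detection only, 2 fail DKO only, 1 fails both."""
        n_study = 4
        beta = beta_frame(np.full((10, 7), 0.9))
        beta.iloc[:, 5:7] = 0.0  # DKO control columns
        det = beta_frame(np.zeros((10, 7)))
        meta = small_cohort_meta(n_study)
        det.iloc[0, :n_study] = 0.9     # detection failures in all study samples
        det.iloc[1, :n_study] = 0.9
        beta.iloc[2, 5:7] = 0.5         # mean DKO beta 0.5 > 0.2
        beta.iloc[3, 5:7] = 0.5
        det.iloc[4, :n_study] = 0.9     # fails both rules
        beta.iloc[4, 5:7] = 0.5
        rep = filter_probes(beta, det, meta)
        oracle = filter_oracle(beta, det, meta)
        assert rep.excluded_detection == frozenset(oracle["det"])
        assert rep.excluded_meth_control == frozenset(oracle["meth"])
        assert rep.excluded_dko == frozenset(oracle["dko"])
        assert (len(rep.excluded_detection), len(rep.excluded_meth_control),
                len(rep.excluded_dko)) == (3, 0, 3)
        assert len(rep.excluded_union) == 5
        assert len(rep.retained) == 5

    def test_oracle_equivalence_on_random_instance(self, rng):
        beta = beta_frame(rng.uniform(0, 1, (300, 9)))
        det = beta_frame(rng.uniform(0, 0.2, (300, 9)))
        meta = small_cohort_meta(6)
        rep = filter_probes(beta, det, meta)
        oracle = filter_oracle(beta, det, meta)
        assert rep.excluded_detection == frozenset(oracle["det"])
        assert rep.excluded_meth_control == frozenset(oracle["meth"])
        assert rep.excluded_dko == frozenset(oracle["dko"])
        union = oracle["det"] | oracle["meth"] | oracle["dko"]
        assert len(rep.retained) == rep.n_input - len(union)

    def test_planted_dko_probes_all_excluded(self, default_dataset):
        cfg, signals, ann, meta, beta = default_dataset
        rep = filter_probes(beta, signals.detection_p, meta)
        planted = set(ann.index[ann["true_dko_fail"]])
        assert planted <= set(rep.excluded_dko)
        assert planted.isdisjoint(rep.retained)

    def test_missing_controls_rejected(self):
        beta = beta_frame(np.full((3, 4), 0.5))
        det = beta_frame(np.zeros((3, 4)))
        meta = small_cohort_meta(4, n_cm=0, n_dko=0)
        with pytest.raises(ValidationError):
            filter_probes(beta, det, meta)


class TestReplicateConcordance:
    def meta_with_pair(self):
        meta = small_cohort_meta(2)
        meta.loc["S00", "replicate_group"] = "rep1"
        meta.loc["S01", "replicate_group"] = "rep1"
        return meta

    def test_identical_vectors_r2_one(self, rng):
        v = rng.uniform(0, 1, 50)
        beta = beta_frame(np.column_stack([v, v, v, v, v]))
        res = replicate_concordance(beta, self.meta_with_pair())
        assert res["r_squared"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_vectors_r2_one(self, rng):
        v = rng.uniform(0, 1, 50)
        beta = beta_frame(np.column_stack([v, 1 - v, v, v, v]))
        res = replicate_concordance(beta, self.meta_with_pair())
        assert res["r_squared"].iloc[0] == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        beta = beta_frame(np.full((10, 5), 0.4))
        with pytest.warns(UserWarning, match="constant"):
            res = replicate_concordance(beta, self.meta_with_pair())
        assert np.isnan(res["r_squared"].iloc[0])

    def test_no_replicates_warns_empty(self):
        beta = beta_frame(np.full((4, 5), 0.4))
        with pytest.warns(UserWarning, match="replicate"):
            res = replicate_concordance(beta, small_cohort_meta(2))
        assert res.empty

    def test_default_noise_mean_r2_above_095(self, default_dataset):
        cfg, signals, ann, meta, beta = default_dataset
        res = replicate_concordance(beta, meta)
        assert len(res) == cfg.n_replicate_pairs
        assert res["r_squared"].mean() > 0.95


class TestExternalAssay:
    def test_external_equal_to_beta_r_one(self, rng):
        beta = beta_frame(rng.uniform(0, 1, (3, 10)))
        external = pd.DataFrame(beta.values, index=["APC", "RASSF1A", "TWIST"],
                                columns=beta.columns)
        pmap = pd.DataFrame({"probe_id": beta.index, "gene": external.index})
        res = external_assay_correlation(beta, external, pmap)
        assert np.allclose(res["r"], 1.0)
        assert res["significant"].all()

    def test_null_calibration_at_alpha(self, rng):
        n = 1000
        beta = beta_frame(rng.uniform(0, 1, (n, 20)))
        external = pd.DataFrame(rng.normal(size=(n, 20)),
                                index=[f"G{i}" for i in range(n)], columns=beta.columns)
        pmap = pd.DataFrame({"probe_id": beta.index, "gene": external.index})
        res = external_assay_correlation(beta, external, pmap, alpha=0.01)
        frac = res["significant"].mean()
        assert abs(frac - 0.01) < 3 * np.sqrt(0.01 * 0.99 / n) + 0.003

    def test_constant_external_skipped(self, rng):
        beta = beta_frame(rng.uniform(0, 1, (1, 8)))
        external = pd.DataFrame(np.full((1, 8), 2.5), index=["APC"], columns=beta.columns)
        pmap = pd.DataFrame({"probe_id": beta.index, "gene": ["APC"]})
        with pytest.warns(UserWarning, match="constant"):
            res = external_assay_correlation(beta, external, pmap)
        assert res.empty
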