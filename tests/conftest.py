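import numpy as np
import pandas as pd
import pytest

from cimpscan import SimConfig, compute_beta, generate_dataset


def flat_means(island=0.3, non_island=0.3):
    """Group means with no tumor contrast, for planting focal differences."""
    return {
        "normal": (0.15, 0.65),
        "tumor_low": (island, non_island),
        "tumor_high": (island, non_island),
    }


def clean_config(**kw) -> SimConfig:
    """A config with no QC-failure planting and no IBC effect, for tests
    where planted artifacts would be confounders."""
    base = dict(
        frac_probes_bad_detection=0.0,
        frac_probes_meth_fail=0.0,
        frac_probes_dko_fail=0.0,
        detection_failure_rate=0.0,
        n_ibc_effect_loci=0,
        n_replicate_pairs=0,
    )
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """A default-condition dataset at reduced probe count (shared, read-only)."""
    cfg = SimConfig(n_probes=2000, seed=20)
    signals, annotation, meta = generate_dataset(cfg)
    beta = compute_beta(signals)
    return cfg, signals, annotation, meta, beta


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def beta_frame(values, probe_prefix="cg", samples=None) -> pd.DataFrame:
    """Small beta matrix from a 2-D array with generated ids."""
    values = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i:04d}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"S{j:02d}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=pd.Index(samples, name="sample_id"))
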