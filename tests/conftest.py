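import numpy as np
import pandas as pd
import pytest

from chronolink import SimConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return SimConfig(seed=11, chrom_length=20_000_000, n_genes=120,
                     min_tss_spacing=10_000, nuc_sites=50,
                     nuc_reads_per_site=200.0)


@pytest.fixture(scope="session")
def small_data(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_data():
    """Full default study conditions (shared; treated as read-only)."""
    return simulate_all(SimConfig(seed=1))


def make_timecourse_row(log2fc, fdr):
    """One-site time-course DataFrame from per-time tuples."""
    from chronolink import TIMEPOINTS
    row = {"chrom": "chrSim", "start": 100, "end": 500, "site_id": "s0",
           "assay": "accessibility"}
    for t, v in zip(TIMEPOINTS, log2fc):
        row[f"log2fc_{t}"] = v
    for t, v in zip(TIMEPOINTS, fdr):
        row[f"fdr_{t}"] = v
    return pd.DataFrame([row])
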