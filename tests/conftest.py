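import numpy as np
import pandas as pd
import pytest

from urmicro import qc
from urmicro.simulate import default_config, simulate_community


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down planted cohort: 20 genera over 80 OTUs, 10/12/10 samples."""
    cfg = default_config(
        seed=11,
        n_otus=80,
        n_genera=20,
        group_sizes={"control": 10, "stone_UR": 12, "tumor_UR": 10},
        depth_mean=20000.0,
        depth_sd=1500.0,
    )
    return simulate_community(cfg)


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    table, tax, meta, tree = small_cohort
    t = qc.filter_otus_min_fraction(qc.filter_samples_min_reads(table, 8000), 1e-4)
    return t, tax, meta.loc[list(t.columns)], tree


@pytest.fixture(scope="session")
def small_rel_genus(small_filtered):
    table, tax, meta, _ = small_filtered
    return qc.aggregate_by_rank(table, tax, "genus"), meta


@pytest.fixture
def tiny_table():
    return pd.DataFrame(
        [[3, 0], [1, 2]], index=["OTU_A", "OTU_B"], columns=["s1", "s2"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
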