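import numpy as np
import pandas as pd
import pytest

from endoprot import SimConfig, simulate_cohort, zscale


@pytest.fixture(scope="session")
def default_cohort():
    """One default simulated cohort (15 HC + 31/42 patients, 1,248 proteins)."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def scaled_patients(default_cohort):
    npx, _, truth = default_cohort
    scaled = zscale(npx)
    return scaled.values.loc[scaled.group == "AD"], truth


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for pipeline-level tests: 3 planted modules,
    120 proteins, full group structure."""
    cfg = SimConfig(
        n_hc=8, n_cluster1=12, n_cluster2=16, n_proteins=120,
        module_sizes=(40, 30, 20), n_ad_up=20, n_stepwise=8, n_unique=4,
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_npx(values: np.ndarray, groups=None, prefix="S"):
    """Small NPXMatrix builder for hand-constructed examples."""
    from endoprot import NPXMatrix

    n, p = values.shape
    idx = pd.Index([f"{prefix}{i + 1}" for i in range(n)], name="SampleID")
    cols = [f"P{j + 1}" for j in range(p)]
    if groups is None:
        groups = ["AD"] * n
    return NPXMatrix(
        pd.DataFrame(values, index=idx, columns=cols),
        pd.Series(groups, index=idx),
    )
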