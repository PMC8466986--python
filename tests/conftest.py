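import pytest

from msatprof.catalog import default_catalog
from msatprof.fragments import CallingParams


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def params():
    return CallingParams()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """One small simulated cohort (seed 11, 40 patients) shared across tests."""
    from msatprof.simdata import SimConfig, generate_cohort

    cfg = SimConfig(seed=11, n_patients=40)
    peaksets, clinical, truth = generate_cohort(cfg, catalog)
    return cfg, peaksets, clinical, truth
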