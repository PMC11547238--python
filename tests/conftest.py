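import numpy as np
import pytest

from melanoliq import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-patient cohort with its 20-donor arm panel and 9-donor
    methylation panel, as one seeded draw."""
    return simulate_cohort(SimulationConfig(seed=2))


@pytest.fixture(scope="session")
def grid_cohort():
    """50 patients with tumor fractions on a regular grid over [0, 0.5],
    used for signal-monotonicity and parameter-recovery checks."""
    cfg = SimulationConfig(seed=11, n_patients=50)
    tfs = np.linspace(0.0, 0.5, 50)
    return simulate_cohort(cfg, tumor_fractions=tfs)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
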