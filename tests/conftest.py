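import numpy as np
import pytest

from callconcord.pipeline import RunConfig, run_simulate
from callconcord.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but non-degenerate cohort: 4 patients, 4 callers."""
    return SimulationConfig(n_patients=4, sites_per_patient=250, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    truth, evidence = simulate_cohort(small_config)
    return truth, evidence


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_config):
    """The small cohort written to disk (VCFs + TSVs + manifest)."""
    out = tmp_path_factory.mktemp("cohort")
    run_simulate(RunConfig(output_dir=out, simulation=small_config))
    return out


@pytest.fixture(scope="session")
def big_cohort():
    """A calibration-sized cohort (10^5 sites, sigma = 0)."""
    config = SimulationConfig(
        n_patients=100, sites_per_patient=1000, eta=0.03, sigma=0.0, seed=5
    )
    truth, evidence = simulate_cohort(config)
    return config, truth, evidence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
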