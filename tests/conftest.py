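import pytest

from neoconcord import io as ncio
from neoconcord import pipeline
from neoconcord.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def conditions():
    return ncio.load_conditions()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-pair synthetic cohort shared by record/table equivalence tests."""
    return simulate_cohort(SimulationConfig(n_pairs=400, seed=11))


@pytest.fixture(scope="session")
def small_pipeline():
    """Full pipeline products on a 2,000-pair cohort."""
    return pipeline.run_pipeline(SimulationConfig(n_pairs=2000, seed=3))
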