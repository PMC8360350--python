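import numpy as np
import pytest

from pigfeed import GrowthTraits, PigObservations
from pigfeed.growth import AVERAGE_PIG
from pigfeed.synthetic import PopulationSpec, sample_traits, simulate_observations


@pytest.fixture(scope="session")
def avg_traits() -> GrowthTraits:
    return AVERAGE_PIG


@pytest.fixture(scope="session")
def small_population():
    """A deterministic 8-pig synthetic population: (truth table, observations)."""
    spec = PopulationSpec(n_pigs=8, seed=42)
    truth = sample_traits(spec)
    return truth, simulate_observations(truth, spec)


@pytest.fixture(scope="session")
def full_population():
    """The default 32-pig synthetic population used by the scenario suites."""
    spec = PopulationSpec(seed=7)
    truth = sample_traits(spec)
    return truth, simulate_observations(truth, spec)


@pytest.fixture()
def clean_observations(avg_traits) -> PigObservations:
    """Noise-free daily record of the average pig over 81 d."""
    days = np.arange(81.0)
    from pigfeed.growth import bw_at

    bw = bw_at(avg_traits, days)
    dfi = np.full(81, 2.5)
    return PigObservations(pig_id="avg", t=days, BW=bw, DFI=dfi)
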