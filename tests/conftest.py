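import numpy as np
import pytest

from platsig import SimulationConfig, build_catalog, simulate_cohort
from platsig.signatures import load_reference_signatures
from platsig.simulate import FIXTURE_SEED, make_fixture_suite


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 18-sample cohort with all five planted signatures."""
    table, truth = simulate_cohort(SimulationConfig(seed=FIXTURE_SEED))
    return table, truth


@pytest.fixture(scope="session")
def default_catalog(default_cohort):
    table, _ = default_cohort
    return build_catalog(table)


@pytest.fixture(scope="session")
def refs():
    return load_reference_signatures()


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out)


def planted_profiles(rng=None):
    """Three well-separated synthetic profiles on disjoint channel blocks."""
    profiles = np.zeros((3, 96))
    profiles[0, 0:8] = 1 / 8
    profiles[1, 40:52] = 1 / 12
    profiles[2, 80:96] = 1 / 16
    return profiles
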