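import numpy as np
import pytest

from bayespbpk import (
    ObservationSet,
    PopulationPKModel,
    default_population_grid,
    load_theophylline_fixture,
)


@pytest.fixture(scope="session")
def grid():
    return default_population_grid()


@pytest.fixture(scope="session")
def theoph():
    return load_theophylline_fixture()


@pytest.fixture(scope="session")
def model(grid, theoph):
    return PopulationPKModel(grid, theoph)


@pytest.fixture(scope="session")
def small_model(grid, theoph):
    """Two-subject model on a reduced sampling grid (fast sampler tests)."""
    import copy

    individuals = []
    for ind in theoph.individuals[:2]:
        ind = copy.deepcopy(ind)
        keep = np.isin(np.round(ind.times_h), [1, 2, 5, 9, 24])
        ind.times_h = ind.times_h[keep]
        ind.conc = ind.conc[keep]
        individuals.append(ind)
    return PopulationPKModel(grid, ObservationSet(individuals))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
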