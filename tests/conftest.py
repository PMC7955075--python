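import numpy as np
import pytest

from pavuln import (
    GridSpec,
    ProtectedArea,
    SpeciesRecord,
    simulate_protected_areas,
)


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec(nrows=20, ncols=20)


@pytest.fixture
def big_grid() -> GridSpec:
    return GridSpec(nrows=100, ncols=100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def one_cell_pa() -> ProtectedArea:
    return ProtectedArea(pa_id="P1", cells=frozenset({(0, 0)}))


def make_species(species_id="s1", group="birds", category="CR", cells=((0, 0),)):
    return SpeciesRecord(
        species_id=species_id,
        group=group,
        category=category,
        range_cells=frozenset(cells),
    )


@pytest.fixture
def fifty_pas(big_grid):
    return simulate_protected_areas(big_grid, n_pas=50, size_range=(4, 16), seed=3)
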