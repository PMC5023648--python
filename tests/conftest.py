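import numpy as np
import pytest

import altiband as ab


@pytest.fixture(scope="session")
def mountain_params():
    return ab.MountainParams(grid_shape=(80, 80), seed=3)


@pytest.fixture(scope="session")
def climate_grid(mountain_params):
    grid = ab.generate_elevation_grid(mountain_params)
    return ab.generate_climate(grid, mountain_params)


@pytest.fixture(scope="session")
def ee_scheme(climate_grid, mountain_params):
    scheme = ab.make_equal_elevation_bands(
        mountain_params.domain_min_elev, mountain_params.domain_max_elev, 100.0)
    scheme = ab.assign_band_areas(scheme, climate_grid)
    return ab.summarize_band_climate(scheme, climate_grid)


@pytest.fixture(scope="session")
def checklist():
    return ab.generate_checklist(ab.ChecklistParams(seed=7), (1350.0, 5050.0))


def random_checklist(rng, n, domain=(1350.0, 5050.0)):
    """A small random checklist for property tests."""
    params = ab.ChecklistParams(
        n_species=n,
        group_proportions=tuple(rng.dirichlet([1, 1, 1])),
        lifeform_proportions=tuple(rng.dirichlet([1, 1, 1])),
        single_record_fraction=float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(2**31)),
    )
    return ab.generate_checklist(params, domain)
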