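import numpy as np
import pytest

from nctscreen import (FieldSimParams, PlateSimParams, default_screen_layout,
                       simulate_field, simulate_plate)


@pytest.fixture(scope="session")
def small_field_params():
    """A modest field: 20 cells, low noise, nuclear DPR stain."""
    return FieldSimParams(field_shape=(512, 512), n_cells=20, noise_sd=2.0,
                          dpr_localization="nuclear")


@pytest.fixture(scope="session")
def small_field(small_field_params):
    return simulate_field(small_field_params, seed=11)


@pytest.fixture(scope="session")
def layout():
    return default_screen_layout("P1")


@pytest.fixture(scope="session")
def null_plate(layout):
    """A plate with no planted effects: test wells behave like PR controls."""
    cells, truth = simulate_plate(
        PlateSimParams(layout=layout, seed=5, well_sd=0.0))
    return cells, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
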