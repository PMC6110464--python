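import numpy as np
import pytest

from seasonniche import (
    ClimateParams,
    GridSpec,
    make_climate_stack,
)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=40, n_cols=40, x_origin=-110.0, y_origin=50.0,
                    cell_size=0.0416)


@pytest.fixture(scope="session")
def small_stack(small_grid):
    return make_climate_stack(small_grid, ClimateParams(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
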