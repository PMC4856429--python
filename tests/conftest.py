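import numpy as np
import pytest

from ecoserv import LandscapeSpec, RasterGrid, generate_landscape
from ecoserv.tables import default_lulc_table, default_soil_k_table


@pytest.fixture(scope="session")
def table():
    return default_lulc_table()


@pytest.fixture(scope="session")
def soil_k():
    return default_soil_k_table()


@pytest.fixture(scope="session")
def small_landscape():
    """80x80 synthetic landscape shared by the integration-style tests."""
    return generate_landscape(LandscapeSpec(n_rows=80, n_cols=80, seed=11))


@pytest.fixture
def flat_dem():
    return RasterGrid(np.full((9, 9), 700.0), cell_size=30.0)
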