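import numpy as np
import pytest

from lv4dflow.grid import GridSpec
from lv4dflow.synthetic import LVFlowParams, make_lv_flow, make_taylor_green


@pytest.fixture(scope="session")
def lv_params():
    return LVFlowParams()


@pytest.fixture(scope="session")
def lv_grid():
    """Desk-scale grid covering the ventricle (2.75 mm voxels, 64 phases
    over one 857 ms cycle)."""
    return GridSpec((-33.0, -52.0, -30.0), (2.75, 2.75, 2.75), (24, 30, 22),
                    0.857 / 64, 64)


@pytest.fixture(scope="session")
def lv_flow(lv_params, lv_grid):
    return make_lv_flow(lv_params, lv_grid)


@pytest.fixture(scope="session")
def taylor_green_32():
    grid = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (32, 32, 32), 0.002, 3)
    flow, pressure = make_taylor_green(grid, amplitude=0.5)
    flow.metadata["periodic"] = True
    return flow, pressure


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
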