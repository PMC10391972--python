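import numpy as np
import pytest

from isomigrate import (
    AssignmentSurface,
    CovarianceSpec,
    FeatherRecord,
    RasterGrid,
    Region,
    WorldScenario,
    calibrate_h_isoscape,
    plant_to_feather_c,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid(rng):
    """10x10 grid of random per-mil values with a few masked cells."""
    values = rng.normal(-60.0, 15.0, size=(10, 10))
    mask = np.ones((10, 10), dtype=bool)
    mask[0, 0] = mask[7, 3] = False
    return RasterGrid(values=values, mask=mask, origin_x=5.0, origin_y=200.0, cell_size=2.5)


@pytest.fixture
def toy_isoscapes():
    """5x5 feather isoscapes over crossed linear H and C gradients."""
    cols = np.tile(np.arange(5.0), (5, 1))
    rows = cols.T
    mask = np.ones((5, 5), dtype=bool)
    h = RasterGrid(values=-120.0 + 10.0 * cols, mask=mask)
    c = RasterGrid(values=-28.0 + 1.0 * rows, mask=mask)
    return calibrate_h_isoscape(h), plant_to_feather_c(c)


@pytest.fixture
def default_cov():
    return CovarianceSpec(sd_h=12.0, sd_c=1.5, rho=0.0)


@pytest.fixture
def record():
    return FeatherRecord(
        id="bird1", species="BARS", site="Saskatoon", population="SK", sex="F",
        d2h_f=-75.0, d13c_f=-21.0, d15n_f=10.5, wing_mm=118.0,
    )


def make_surface(prob_rows, individual_id="x", **geo):
    """Build an AssignmentSurface from explicit probabilities (NaN = invalid)."""
    values = np.asarray(prob_rows, dtype=float)
    mask = np.isfinite(values)
    grid = RasterGrid(values=np.nan_to_num(values), mask=mask, **geo)
    return AssignmentSurface(prob=grid, individual_id=individual_id)


@pytest.fixture
def flat_scenario():
    """Small featureless world with two disjoint molt regions."""
    return WorldScenario(
        shape=(40, 40), h_slope=1.2, c_slope=0.15,
        regions=[Region("w", "disc", (20.0, 8.0, 5.0)), Region("e", "disc", (20.0, 32.0, 5.0))],
    )
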