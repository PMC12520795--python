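import numpy as np
import pandas as pd
import pytest

from invasdm import Grid, RasterStack


@pytest.fixture
def small_grid():
    """10x10 grid, 100 m cells, left 6 columns invasive / right 4 native."""
    mask = np.full((10, 10), "native", dtype=object)
    mask[:, :6] = "invasive"
    return Grid(n_rows=10, n_cols=10, cell_size_m=100.0, region_mask=mask)


@pytest.fixture
def toy_stack(small_grid):
    """Three deterministic layers with one NA hole at (0, 0)."""
    rng = np.random.default_rng(123)
    layers = {
        "elev": rng.standard_normal(small_grid.shape),
        "precip": rng.standard_normal(small_grid.shape),
        "ndvi": rng.standard_normal(small_grid.shape),
    }
    for arr in layers.values():
        arr[0, 0] = np.nan
    return RasterStack(grid=small_grid, layers=layers)


def make_records(xs, ys, cus, regions, **extra):
    n = len(xs)
    base = {
        "longitude": xs,
        "latitude": ys,
        "coordinate_uncertainty_m": cus,
        "event_date": ["2020-01-01"] * n,
        "basis_of_record": ["human_observation"] * n,
        "region": regions,
    }
    base.update(extra)
    return pd.DataFrame(base)
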