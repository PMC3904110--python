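import numpy as np
import pandas as pd
import pytest

from riskconn.grid import BOLDSeries, BrainGrid
from riskconn import synthetic


@pytest.fixture
def small_grid():
    return BrainGrid(dims=(6, 6, 4))


@pytest.fixture
def rng():
    return np.random.default_rng(20140128)


@pytest.fixture
def toy_bold(small_grid, rng):
    """Small full-mask BOLD series of independent noise, TR 2 s."""
    data = rng.standard_normal(small_grid.dims + (40,))
    mask = np.ones(small_grid.dims, dtype=bool)
    return BOLDSeries(data=data, tr=2.0, grid=small_grid, mask=mask)


@pytest.fixture(scope="session")
def cohort_table():
    """A 289-subject questionnaire table with the default planted model."""
    roster = synthetic.generate_roster(289, sex_split=(131, 158), seed=77)
    table, latent = synthetic.generate_questionnaire_scores(roster, seed=78)
    return table, latent


def make_bold_from_series(series_by_voxel, dims, tr=2.0, grid=None):
    """Build a BOLDSeries with explicit per-voxel series; the mask covers
    exactly the listed voxels."""
    grid = grid or BrainGrid(dims=dims)
    some = next(iter(series_by_voxel.values()))
    data = np.zeros(tuple(dims) + (len(some),))
    mask = np.zeros(dims, dtype=bool)
    for vox, series in series_by_voxel.items():
        data[vox] = series
        mask[vox] = True
    return BOLDSeries(data=data, tr=tr, grid=grid, mask=mask)
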