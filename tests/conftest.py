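import numpy as np
import pandas as pd
import pytest

import epizone as ez


@pytest.fixture(scope="session")
def grid():
    return ez.build_zone_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(20240713)


def make_map(values, grid, subject="s1", eye="OD", index=1, canonical=True):
    """ETMap from a scalar, array or alias->value mapping."""
    if np.isscalar(values):
        series = pd.Series(float(values), index=list(grid.aliases))
    elif isinstance(values, dict):
        series = pd.Series(values).reindex(list(grid.aliases))
    else:
        series = pd.Series(np.asarray(values, dtype=float), index=list(grid.aliases))
    return ez.ETMap(
        subject_id=subject,
        eye=eye,
        measurement_index=index,
        values=series,
        canonical=canonical,
    )


def random_map(rng, grid, low=40.0, high=70.0, **kw):
    return make_map(rng.uniform(low, high, size=len(grid)), grid, **kw)


@pytest.fixture
def map_factory(grid):
    return lambda values, **kw: make_map(values, grid, **kw)


@pytest.fixture
def random_map_factory(grid, rng):
    return lambda **kw: random_map(rng, grid, **kw)
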