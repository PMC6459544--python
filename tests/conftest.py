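import math

import numpy as np
import pandas as pd
import pytest

from epipattern import (
    DEFAULT_GEOMETRY,
    ConditionPreset,
    default_presets,
    make_geometry,
)


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def wt_preset():
    return default_presets()[0]


@pytest.fixture(scope="session")
def small_geometry():
    """Small sector for fast generator tests."""
    return make_geometry(radius=150.0, sector_center=-math.pi / 2, sector_halfwidth=1.6875)


@pytest.fixture(scope="session")
def small_preset():
    """Preset scaled to the small geometry (same density as the default)."""
    return ConditionPreset(name="small", n_stem_mean=170.0, domain_radius_frac=0.9)


def cells_from_arrays(
    xy: np.ndarray,
    diameter: float | np.ndarray = 10.0,
    dlc: bool | np.ndarray = True,
    p63: bool | np.ndarray = True,
    brdu: bool | np.ndarray = False,
    embryo_id: str = "e0",
    condition: str = "test",
) -> pd.DataFrame:
    """Build a minimal cell table from coordinate arrays (test helper)."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    n = len(xy)

    def _col(v, dtype):
        arr = np.asarray(v)
        if arr.ndim == 0:
            arr = np.full(n, v)
        return arr.astype(dtype)

    return pd.DataFrame(
        {
            "embryo_id": [embryo_id] * n,
            "cell_id": np.arange(n),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "diameter_um": _col(diameter, float),
            "p63": _col(p63, bool),
            "dlc": _col(dlc, bool),
            "brdu": _col(brdu, bool),
            "condition": [condition] * n,
        }
    )
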