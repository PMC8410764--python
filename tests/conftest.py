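import numpy as np
import pandas as pd
import pytest

from laketrack import LakeGrid, LakeScenario, make_lake
from shapely.geometry import Point

# small basin keeps KDE grids and simulations cheap in unit tests
SMALL_SCENARIO = LakeScenario(
    name="TST",
    max_depth=20.0,
    surface_area=20e4,
    macrophyte_profile={
        "June": [((0.0, 6.0), (50.0, 80.0), (30.0, 150.0))],
        "September": [((0.0, 6.0), (50.0, 80.0), (30.0, 150.0))],
    },
)


@pytest.fixture(scope="session")
def small_lake() -> LakeGrid:
    return make_lake(SMALL_SCENARIO, seed=7)


@pytest.fixture(scope="session")
def flat_lake() -> LakeGrid:
    """A 1 km flat-bottomed 10 m deep basin for hand-computable lookups."""
    cell = 10.0
    centers = np.arange(-50, 51) * cell
    depths = np.full((centers.size, centers.size), 10.0)
    xg, yg = np.meshgrid(centers, centers)
    r = np.hypot(xg, yg)
    R = 500.0
    depths[r >= R] = 0.0
    return LakeGrid(
        depths=depths,
        cell=cell,
        x_centers=centers.astype(float),
        y_centers=centers.astype(float),
        shoreline=Point(0, 0).buffer(R, quad_segs=90),
        name="flat",
    )


@pytest.fixture(scope="session")
def twilight_0521() -> pd.DataFrame:
    """One fixed twilight row: civil dawn 05:00, civil dusk 21:00."""
    return pd.DataFrame(
        [
            {
                "date": "2015-06-01",
                "dawn": "05:00:00",
                "dusk": "21:00:00",
                "sunrise": "05:40:00",
                "sunset": "20:20:00",
            }
        ]
    )


def qpos_row(tag, t, x=np.nan, y=np.nan, depth=np.nan, interpolated=False,
             n_fixes=0, n_depth=0, **extra):
    row = {
        "tag_id": tag,
        "interval_start": pd.Timestamp(t),
        "x": x,
        "y": y,
        "depth": depth,
        "n_fixes": n_fixes,
        "n_depth_fixes": n_depth,
        "interpolated": interpolated,
    }
    row.update(extra)
    return row
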