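import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from stopovermap import (
    Grid,
    LandscapeParams,
    LayerStack,
    StreamFeature,
    WetlandFeature,
    generate_landscape,
)


def make_grid(values, cell_size=90.0, mask=None, origin=None):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (0.0, values.shape[0] * cell_size)
    return Grid(values, mask, cell_size, origin)


def make_stack(rows=6, cols=6, cell_size=90.0, streams=None, wetlands=None, **grids):
    """A complete layer stack with constant defaults, overridable per layer."""
    defaults = {
        "elevation": 2000.0,
        "aspect": 0.0,
        "land_cover": 0.0,
        "bare_ground": 0.0,
        "cottonwood": 0.0,
        "willow": 0.0,
        "prairie_dog": 0.0,
        "wind_direction_category": 0.0,
        "crops": 0.0,
        "flyway_mask": 0.0,
    }
    out = {}
    for name, default in defaults.items():
        arr = grids.get(name, default)
        arr = np.broadcast_to(np.asarray(arr, dtype=float), (rows, cols)).copy()
        out[name] = make_grid(arr, cell_size)
    stack = LayerStack(grids=out, streams=streams or [], wetlands=wetlands or [])
    stack.validate()
    return stack


@pytest.fixture(scope="session")
def default_stack():
    """The generator's default landscape (150x150 at 90 m)."""
    return generate_landscape(LandscapeParams(seed=11))


@pytest.fixture(scope="session")
def oracle_stack6():
    """A 6x6 hand-built landscape for the wetland-model arithmetic oracle.

    One large river down column 2; 398 micro wetlands (1 ha) at a single
    point plus a 20-ha wetland footprint in cell (5,5) and an 8-ha one in
    cell (0,4); banded elevation and crops; flyway east of column 2.
    """
    rows = cols = 6
    elevation = np.repeat([[2000.0], [2000.0], [2600.0], [2600.0], [2800.0], [2800.0]], 6, axis=1)
    crops = np.repeat([[1.0], [1.0], [2.0], [2.0], [0.0], [0.0]], 6, axis=1)
    flyway = np.zeros((rows, cols))
    flyway[:, 3:] = 1.0
    river = StreamFeature(
        LineString([(225.0, 540.0), (225.0, 0.0)]), order=7, perennial=True, large_river=True
    )
    wetlands = [
        WetlandFeature(box(465.0, 15.0, 495.0, 45.0), area_ha=20.0, kind="lacustrine"),
        WetlandFeature(box(380.0, 470.0, 420.0, 500.0), area_ha=8.0),
    ]
    micro = Point(45.0, 495.0).buffer(5.0, quad_segs=4)
    wetlands += [WetlandFeature(micro, area_ha=1.0) for _ in range(398)]
    return make_stack(
        rows,
        cols,
        elevation=elevation,
        crops=crops,
        flyway_mask=flyway,
        streams=[river],
        wetlands=wetlands,
    )
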