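import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from wrastic.grid import RasterGrid
from wrastic.io import load_reference_table


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20210531)


def make_raster(values, cell=25.0, nodata=-9999.0, crs="local-metre"):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, x0=0.0, y0=values.shape[0] * cell, cell=cell,
                      crs=crs, nodata=nodata)


@pytest.fixture
def irregular_polygon():
    # a concave pentagon sitting inside a 64x64 grid at 25 m cells
    return Polygon([(100, 100), (1400, 250), (1200, 900), (700, 620), (250, 1300)])


def brute_force_zone_values(r, zone):
    """Independent scalar-loop oracle for zonal cell selection."""
    vals = []
    nrows, ncols = r.shape
    for i in range(nrows):
        for j in range(ncols):
            x = r.x0 + (j + 0.5) * r.cell
            y = r.y0 - (i + 0.5) * r.cell
            v = r.values[i, j]
            if v == r.nodata or (isinstance(v, float) and not np.isfinite(v)):
                continue
            if Point(x, y).within(zone):
                vals.append(v)
    return np.asarray(vals)
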