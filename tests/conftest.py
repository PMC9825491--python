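import datetime as dt

import numpy as np
import pytest

from halfmoon import SimulationConfig, simulate_dataset
from halfmoon.raster import InterventionPolygon, SceneStack
from shapely.geometry import box


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic study: 2 sites x 2 polygons on a 64x64 grid."""
    return SimulationConfig(
        grid_shape=(64, 64),
        n_sites=2,
        polygons_per_site=2,
        cloud_prob=0.2,
        noise_sd=0.02,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No clouds, no noise, no interannual rainfall variability."""
    return SimulationConfig(
        grid_shape=(64, 64),
        n_sites=2,
        polygons_per_site=2,
        cloud_prob=0.0,
        noise_sd=0.0,
        rainfall_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config)


def make_stack(ndvi_grids, dates=None, qa=None, transform=(0.0, 30.0, 0.0, 0.0, 0.0, -30.0)):
    """Build a SceneStack whose NDVI equals the given grids (red fixed 0.2)."""
    ndvi = np.asarray(ndvi_grids, dtype=np.float64)
    if ndvi.ndim == 2:
        ndvi = ndvi[None]
    n = ndvi.shape[0]
    if dates is None:
        dates = [dt.date(2015, 1, 1) + dt.timedelta(days=16 * i) for i in range(n)]
    red = np.full(ndvi.shape, 0.2)
    nir = 0.2 * (1 + ndvi) / (1 - ndvi)
    if qa is None:
        qa = np.zeros(ndvi.shape, dtype=np.uint8)
    return SceneStack(
        dates=list(dates), red=red, nir=nir, qa=np.asarray(qa, dtype=np.uint8),
        transform=transform, crs="EPSG:32632",
    )


def make_polygon(r0, c0, side, site="siteA", pid=0, year=2015, zone="pastoral",
                 transform=(0.0, 30.0, 0.0, 0.0, 0.0, -30.0)):
    """Axis-aligned square polygon covering pixels [r0:r0+side, c0:c0+side]."""
    x0, dx, _, y0, _, dy = transform
    geom = box(x0 + c0 * dx, y0 + (r0 + side) * dy, x0 + (c0 + side) * dx, y0 + r0 * dy)
    return InterventionPolygon(
        site=site, polygon_id=pid, geometry=geom, intervention_year=year,
        zone=zone, area_ha=side * side * 0.09,
    )
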