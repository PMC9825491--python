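"""Synthetic scene/polygon/rainfall generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not radiometric realism:

* a 16-day-revisit stack of red/NIR reflectance scenes on a 30 m grid,
* pixelwise NDVI = raised-cosine seasonal cycle peaking 1 September
  + rainfall coupling x (annual total - climatological mean)
  + a step ``effect_size`` inside intervened polygons during
    growing-season months of post-intervention years
  + Gaussian noise,
* per-pixel independent Bernoulli cloud flags in the QA band,
* pentad rainfall whose annual totals are truncated-normal and whose
  Jun-Sept share is >= 90% of the year.

Reflectance pairs are synthesized by fixing red at 0.2 and inverting the
NDVI target for NIR; any pair reproducing the target NDVI is equivalent for
the downstream analysis. The injected effect and the cloud masks are
returned as :class:`GroundTruth`, the oracle for recovery tests.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import box

from .config import GROWING_SEASON_MONTHS, MONTHLY_RAIN_FRACTIONS, SimulationConfig
from .rainfall import RainfallSeries
from .raster import InterventionPolygon, SceneStack, polygon_pixel_mask

_PEAK_DOY = 244  # 1 September
_YEAR_DAYS = 365.25
_RED_REFLECTANCE = 0.2
_POLYGON_SIDES_PX = (13, 14, 15)  # >= 150 pixels (~13 ha) each at 30 m
_INTERVENTION_OFFSETS = (3, 8, 5)  # years after study start: 2013/2018/2015

# substream ids for the top-level seed
_STREAM_RAIN = 1
_STREAM_CLOUD = 2
_STREAM_NOISE = 3


@dataclass
class GroundTruth:
    """What the generator actually injected; oracle for recovery tests."""

    effects: dict[int, float]  # polygon_id -> step effect (NDVI units)
    intervention_years: dict[int, int]
    annual_rainfall: dict[int, float]  # mm
    cloud_masks: np.ndarray  # (n_scenes, rows, cols) bool

    def effect_at(self, polygon_id: int, year: int, month: int) -> float:
        """True effect for a polygon at a calendar (year, month); zero
        before the intervention year and outside the growing season."""
        if year < self.intervention_years[polygon_id]:
            return 0.0
        if month not in GROWING_SEASON_MONTHS:
            return 0.0
        return self.effects[polygon_id]


def seasonal_cycle(dates: np.ndarray | list[dt.date]) -> np.ndarray:
    """Raised-cosine seasonal factor in [0, 1], peaking on 1 September."""
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - _PEAK_DOY) / _YEAR_DAYS))


def scene_dates(config: SimulationConfig) -> list[dt.date]:
    """Acquisition dates: every ``revisit_days`` from 1 Jan of start_year."""
    d = dt.date(config.start_year, 1, 1)
    end = dt.date(config.end_year, 12, 31)
    step = dt.timedelta(days=config.revisit_days)
    out = []
    while d <= end:
        out.append(d)
        d += step
    return out


def default_intervention_years(config: SimulationConfig) -> dict[int, int]:
    """Rotation of intervention years within each site.

    Offsets (3, 8, 5) from the study start give 2013/2018/2015 under the
    default 2010-2020 span: the first two polygons of every site are always
    a >=3-year-gap control/experiment pair (whatever the per-site count)
    and no polygon is intervened in the final study year.
    """
    years = {}
    pid = 0
    for _site in range(config.n_sites):
        for k in range(config.polygons_per_site):
            off = _INTERVENTION_OFFSETS[k % len(_INTERVENTION_OFFSETS)]
            year = min(config.start_year + off, config.end_year - 1)
            years[pid] = year
            pid += 1
    return years


def generate_polygons(config: SimulationConfig) -> list[InterventionPolygon]:
    """Non-overlapping square polygons grouped into per-site blocks.

    Sites tile the raster in blocks; polygons are laid out row-major inside
    their block with a margin, each >= ~15 ha so control-pair area criteria
    are satisfiable. Zones alternate pastoral/agricultural per site (all
    polygons of a site share the zone, as pairing requires).
    """
    rows, cols = config.grid_shape
    n_block_cols = int(np.ceil(np.sqrt(config.n_sites)))
    n_block_rows = int(np.ceil(config.n_sites / n_block_cols))
    block_h = rows // n_block_rows
    block_w = cols // n_block_cols
    margin = 2
    years = (
        dict(config.intervention_years)
        if config.intervention_years is not None
        else default_intervention_years(config)
    )
    x0, dx, _, y0, _, dy = config.transform()
    polygons: list[InterventionPolygon] = []
    pid = 0
    for s in range(config.n_sites):
        br, bc = divmod(s, n_block_cols)
        r = br * block_h + margin
        c = bc * block_w + margin
        row_height = 0
        for k in range(config.polygons_per_site):
            side = _POLYGON_SIDES_PX[k % len(_POLYGON_SIDES_PX)]
            if c + side > (bc + 1) * block_w - margin:
                # wrap to next row inside the block
                c = bc * block_w + margin
                r += row_height + margin
                row_height = 0
            if r + side > (br + 1) * block_h - margin:
                raise ValueError(
                    f"cannot place {config.polygons_per_site} polygons in site "
                    f"block {s} without overlap; enlarge grid_shape"
                )
            geom = box(
                x0 + c * dx,
                y0 + (r + side) * dy,
                x0 + (c + side) * dx,
                y0 + r * dy,
            )
            if pid not in years:
                raise ValueError(f"no intervention year supplied for polygon {pid}")
            polygons.append(
                InterventionPolygon(
                    site=f"site{s + 1:02d}",
                    polygon_id=pid,
                    geometry=geom,
                    intervention_year=years[pid],
                    zone="pastoral" if s % 2 == 0 else "agricultural",
                    area_ha=side * side * config.pixel_size**2 / 10_000.0,
                )
            )
            c += side + margin
            row_height = max(row_height, side)
            pid += 1
    return polygons


def generate_rainfall(config: SimulationConfig, n_years: int | None = None) -> RainfallSeries:
    """Pentad rainfall with truncated-normal annual totals.

    Annual totals follow Normal(rainfall_mean, rainfall_sd) truncated at
    zero. Monthly shares follow the fixed Sahelian climatology (92% in
    Jun-Sept); within each month the six pentads split the monthly total by
    a Dirichlet draw, so individual pentads vary while the seasonal
    concentration is preserved for every year.
    """
    rng = config.rng(_STREAM_RAIN)
    years = (
        list(config.years)
        if n_years is None
        else list(range(config.start_year, config.start_year + n_years))
    )
    if config.rainfall_sd > 0:
        a = (0.0 - config.rainfall_mean) / config.rainfall_sd
        totals = stats.truncnorm.rvs(
            a, np.inf, loc=config.rainfall_mean, scale=config.rainfall_sd,
            size=len(years), random_state=rng,
        )
    else:
        totals = np.full(len(years), config.rainfall_mean)
    records = []
    for year, total in zip(years, totals):
        for month in range(1, 13):
            month_total = total * MONTHLY_RAIN_FRACTIONS[month - 1]
            weights = rng.dirichlet(np.ones(6))
            for day, w in zip((1, 6, 11, 16, 21, 26), weights):
                records.append(
                    {
                        "date": dt.date(year, month, day),
                        "rainfall_mm": month_total * w,
                    }
                )
    df = pd.DataFrame.from_records(records)
    return RainfallSeries(
        pentads=df,
        long_term_mean=config.rainfall_mean,
        long_term_sd=config.rainfall_sd,
    )


def generate_scene_stack(
    config: SimulationConfig,
    polygons: list[InterventionPolygon] | None = None,
    rainfall: RainfallSeries | None = None,
) -> tuple[SceneStack, GroundTruth]:
    """Simulate the dated red/NIR/QA stack and return it with its truth.

    ``polygons``/``rainfall`` default to the generator's own deterministic
    outputs for the same config, so calling the three generators separately
    or together yields one consistent dataset.
    """
    if polygons is None:
        polygons = generate_polygons(config)
    if rainfall is None:
        rainfall = generate_rainfall(config)
    dates = scene_dates(config)
    rows, cols = config.grid_shape
    n = len(dates)

    annual = rainfall.annual_totals()
    rain_by_year = {int(y): float(v) for y, v in annual.items()}

    season = seasonal_cycle(dates)  # (n,)
    rain_anom = np.array(
        [rain_by_year[d.year] - config.rainfall_mean for d in dates]
    )
    base = (
        config.baseline_ndvi
        + config.seasonal_amplitude * season
        + config.rain_coupling * rain_anom
    )  # (n,)

    ndvi = np.broadcast_to(base[:, None, None], (n, rows, cols)).copy()

    # step effect inside intervened polygons, growing-season months only
    masks = {
        p.polygon_id: polygon_pixel_mask(p.geometry, config.transform(), (rows, cols))
        for p in polygons
    }
    for p in polygons:
        active = np.array(
            [
                d.year >= p.intervention_year and d.month in GROWING_SEASON_MONTHS
                for d in dates
            ]
        )
        if active.any():
            tt = np.nonzero(active)[0]
            rr, cc = np.nonzero(masks[p.polygon_id])
            ndvi[tt[:, None], rr[None, :], cc[None, :]] += config.effect_size

    if config.noise_sd > 0:
        ndvi += config.rng(_STREAM_NOISE).normal(0.0, config.noise_sd, ndvi.shape)
    np.clip(ndvi, -0.999, 0.999, out=ndvi)

    red = np.full(ndvi.shape, _RED_REFLECTANCE, dtype=np.float32)
    nir = (_RED_REFLECTANCE * (1.0 + ndvi) / (1.0 - ndvi)).astype(np.float32)

    clouds = config.rng(_STREAM_CLOUD).random(ndvi.shape) < config.cloud_prob
    qa = clouds.astype(np.uint8)  # 1 = cloud, 0 = clear

    stack = SceneStack(
        dates=dates,
        red=red,
        nir=nir,
        qa=qa,
        transform=config.transform(),
        crs=config.crs,
    )
    truth = GroundTruth(
        effects={p.polygon_id: config.effect_size for p in polygons},
        intervention_years={p.polygon_id: p.intervention_year for p in polygons},
        annual_rainfall=rain_by_year,
        cloud_masks=clouds,
    )
    return stack, truth


@dataclass
class SimulatedDataset:
    """One consistent synthetic study: scenes, polygons, rainfall, truth."""

    config: SimulationConfig
    stack: SceneStack
    polygons: list[InterventionPolygon]
    rainfall: RainfallSeries
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    polygons = generate_polygons(config)
    rainfall = generate_rainfall(config)
    stack, truth = generate_scene_stack(config, polygons=polygons, rainfall=rainfall)
    return SimulatedDataset(
        config=config, stack=stack, polygons=polygons, rainfall=rainfall, truth=truth
    )


def deterministic_polygon_ndvi(
    config: SimulationConfig,
    dates: list[dt.date],
    rain_by_year: Mapping[int, float],
    intervention_year: int | None = None,
) -> np.ndarray:
    """Noise-free NDVI a polygon's mean would follow; test oracle."""
    season = seasonal_cycle(dates)
    anom = np.array([rain_by_year[d.year] - config.rainfall_mean for d in dates])
    out = config.baseline_ndvi + config.seasonal_amplitude * season + config.rain_coupling * anom
    if intervention_year is not None:
        active = np.array(
            [
                d.year >= intervention_year and d.month in GROWING_SEASON_MONTHS
                for d in dates
            ]
        )
        out = out + np.where(active, config.effect_size, 0.0)
    return out
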