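"""Generator behaviour: determinism, injected structure, rainfall regime."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

import halfmoon as hm
from halfmoon.config import GROWING_SEASON_MONTHS
from halfmoon.synthetic import (
    default_intervention_years,
    deterministic_polygon_ndvi,
    scene_dates,
    seasonal_cycle,
)


def test_same_seed_bit_identical(small_config):
    a = hm.simulate_dataset(small_config)
    b = hm.simulate_dataset(small_config)
    assert np.array_equal(a.stack.red, b.stack.red)
    assert np.array_equal(a.stack.nir, b.stack.nir)
    assert np.array_equal(a.stack.qa, b.stack.qa)
    pd.testing.assert_frame_equal(a.rainfall.pentads, b.rainfall.pentads)
    assert [p.geometry.wkt for p in a.polygons] == [p.geometry.wkt for p in b.polygons]


def test_different_seed_differs(small_config):
    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    a = hm.simulate_dataset(small_config)
    b = hm.simulate_dataset(other)
    assert not np.array_equal(a.stack.qa, b.stack.qa)


def test_no_effect_no_noise_series_repeats_across_years(clean_config):
    """Without effect, noise, clouds or rainfall variability, a polygon's
    NDVI depends only on day-of-year: matching DOYs agree across years."""
    cfg = dataclasses.replace(clean_config, effect_size=0.0)
    ds = hm.simulate_dataset(cfg)
    series = hm.zonal_aggregate(ds.stack, ds.polygons, mask_flags=(1,))
    one = series[series["polygon_id"] == ds.polygons[0].polygon_id].copy()
    one["doy"] = pd.to_datetime(one["date"]).dt.dayofyear
    spread = one.groupby("doy")["ndvi_mean"].agg(np.ptp)
    # several years share each DOY under the 16-day cadence from 1 Jan
    assert (spread < 1e-5).all()


def test_all_cloud_means_all_missing(clean_config):
    cfg = dataclasses.replace(clean_config, cloud_prob=1.0)
    ds = hm.simulate_dataset(cfg)
    series = hm.zonal_aggregate(ds.stack, ds.polygons, mask_flags=(1,))
    assert series["ndvi_mean"].isna().all()
    monthly = hm.monthly_composite(series)
    assert monthly["ndvi"].isna().all()
    assert (monthly["n_obs"] == 0).all()


def test_cloud_fraction_binomial(small_dataset):
    """Masked-pixel count per scene ~ Binomial(n_pixels, cloud_prob)."""
    cfg = small_dataset.config
    n_pix = cfg.grid_shape[0] * cfg.grid_shape[1]
    assert n_pix >= 4096
    frac = small_dataset.stack.qa.reshape(small_dataset.stack.n_scenes, -1).mean(axis=1)
    sigma = np.sqrt(cfg.cloud_prob * (1 - cfg.cloud_prob) / n_pix)
    assert (np.abs(frac - cfg.cloud_prob) < 3 * sigma).mean() > 0.95
    # and the grand mean is far inside 3 sigma of the pooled count
    pooled_sigma = sigma / np.sqrt(small_dataset.stack.n_scenes)
    assert abs(frac.mean() - cfg.cloud_prob) < 3 * pooled_sigma


def test_ground_truth_effect_zero_before_intervention(small_dataset):
    truth = small_dataset.truth
    for pid, year in truth.intervention_years.items():
        assert truth.effect_at(pid, year - 1, 9) == 0.0
        assert truth.effect_at(pid, year, 9) == truth.effects[pid]
        assert truth.effect_at(pid, year + 1, 3) == 0.0  # dry season


def test_effect_recovery_against_ground_truth():
    """Post-pre peak-NDVI difference over >=5 polygons recovers the 0.10
    injected effect within +-0.02 (noise_sd 0.02, fixed seed)."""
    cfg = hm.SimulationConfig(
        grid_shape=(96, 96), n_sites=2, polygons_per_site=3,
        effect_size=0.10, noise_sd=0.02, cloud_prob=0.1, rainfall_sd=0.0,
        seed=42,
    )
    ds = hm.simulate_dataset(cfg)
    series = hm.zonal_aggregate(ds.stack, ds.polygons, mask_flags=(1,))
    peaks = hm.annual_peak(series)
    diffs = []
    for p in ds.polygons:
        pp = peaks[peaks["polygon_id"] == p.polygon_id]
        before = pp[pp["year"] < p.intervention_year]["peak"]
        after = pp[pp["year"] > p.intervention_year]["peak"]
        diffs.append(after.mean() - before.mean())
    assert len(diffs) >= 5
    assert np.mean(diffs) == pytest.approx(cfg.effect_size, abs=0.02)


def test_invalid_ndvi_range_rejected():
    with pytest.raises(ValueError, match="leaves"):
        hm.SimulationConfig(baseline_ndvi=0.6, seasonal_amplitude=0.35, effect_size=0.1)


@pytest.mark.parametrize("seed", [0, 1, 99])
def test_rainy_season_share_at_least_90pct(seed):
    cfg = hm.SimulationConfig(seed=seed)
    rain = hm.generate_rainfall(cfg)
    monthly = rain.monthly_totals()
    for year, grp in monthly.groupby("year"):
        wet = grp[grp["month"].isin([6, 7, 8, 9])]["rainfall_mm"].sum()
        assert wet / grp["rainfall_mm"].sum() >= 0.90


def test_rainfall_sd_zero_is_exact_mean(clean_config):
    rain = hm.generate_rainfall(clean_config)
    totals = rain.annual_totals()
    assert np.allclose(totals, clean_config.rainfall_mean, rtol=1e-12)


def test_rainfall_long_run_mean():
    """1000 simulated years: sample mean within mean +- 7 mm (CLT bound)."""
    cfg = hm.SimulationConfig(rainfall_mean=450.0, rainfall_sd=70.0, seed=5)
    rain = hm.generate_rainfall(cfg, n_years=1000)
    totals = rain.annual_totals()
    assert len(totals) == 1000
    assert abs(totals.mean() - 450.0) < 7.0
    assert (totals >= 0).all()


def test_polygons_disjoint_and_on_grid(small_dataset):
    polys = small_dataset.polygons
    sites = {p.site for p in polys}
    assert len(sites) == small_dataset.config.n_sites
    for i, a in enumerate(polys):
        for b in polys[i + 1:]:
            assert not a.geometry.intersects(b.geometry) or a.geometry.touches(b.geometry)
    assert all(p.area_ha >= 13.0 for p in polys)


def test_fourteen_polygons_per_site_supported():
    cfg = hm.SimulationConfig(grid_shape=(128, 128), n_sites=1, polygons_per_site=14)
    polys = hm.generate_polygons(cfg)
    assert len(polys) == 14


def test_overcrowded_grid_fails():
    with pytest.raises(ValueError, match="without overlap"):
        hm.generate_polygons(
            hm.SimulationConfig(grid_shape=(32, 32), n_sites=4, polygons_per_site=3)
        )


def test_deterministic_series_oracle(clean_dataset):
    """Zonal means on clean data equal the closed-form seasonal curve."""
    ds = clean_dataset
    series = hm.zonal_aggregate(ds.stack, ds.polygons, mask_flags=(1,))
    poly = ds.polygons[0]
    got = series[series["polygon_id"] == poly.polygon_id]["ndvi_mean"].to_numpy()
    want = deterministic_polygon_ndvi(
        ds.config, ds.stack.dates, ds.truth.annual_rainfall, poly.intervention_year
    )
    # float32 reflectance round-trip limits agreement
    assert np.allclose(got, want, atol=1e-5)


def test_seasonal_cycle_peaks_in_peak_window():
    import datetime as dt

    dates = [dt.date(2015, 1, 1) + dt.timedelta(days=d) for d in range(365)]
    s = seasonal_cycle(dates)
    peak_date = dates[int(np.argmax(s))]
    assert peak_date.month in (8, 9, 10)
    assert s.min() >= 0 and s.max() <= 1


def test_default_intervention_years_leave_post_years():
    cfg = hm.SimulationConfig()
    years = default_intervention_years(cfg)
    assert set(years.values()) == {2013, 2015, 2018}
    assert all(cfg.start_year <= y < cfg.end_year for y in years.values())


def test_scene_cadence(small_config):
    dates = scene_dates(small_config)
    gaps = {(b - a).days for a, b in zip(dates, dates[1:])}
    assert gaps == {small_config.revisit_days}
    assert dates[0].year == small_config.start_year
    assert dates[-1].year == small_config.end_year
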