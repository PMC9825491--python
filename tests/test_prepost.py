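"""Pre/post split, site aggregation, tests, rainfall ops, regression."""
import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import halfmoon as hm
from halfmoon import (
    ExcludedPolygonError,
    ndvi_rain_regression,
    percent_difference,
    prepost_ttest,
    rainfall_anomaly,
    seasonal_rain_total,
    site_mean_peak,
    split_pre_post,
    summarize_site_table,
)
from halfmoon.datasets import load_site_summary
from halfmoon.rainfall import RainfallSeries, pentad_starts


def make_rain(totals_by_year, mean=450.0, sd=70.0):
    rows = []
    for year, total in totals_by_year.items():
        starts = pentad_starts(year)
        for d in starts:
            rows.append({"date": d, "rainfall_mm": total / len(starts)})
    return RainfallSeries(pd.DataFrame(rows), long_term_mean=mean, long_term_sd=sd)


class TestSplitPrePost:
    def test_mid_study_intervention(self):
        before, after = split_pre_post(2015, 2010, 2020)
        assert before == [2010, 2011, 2012, 2013, 2014]
        assert after == [2016, 2017, 2018, 2019, 2020]

    def test_final_year_polygon_excluded(self):
        with pytest.raises(ExcludedPolygonError):
            split_pre_post(2020, 2010, 2020)

    def test_counting(self):
        before, after = split_pre_post(2013, 2010, 2020)
        assert len(before) == 3 and len(after) == 7

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            split_pre_post(2009, 2010, 2020)


def test_site_mean_peak_single_polygon():
    peaks = pd.DataFrame(
        {"site": "s", "polygon_id": 0, "year": [2011, 2012], "peak": [0.2, 0.3]}
    )
    mean, se, n = site_mean_peak(peaks, [2011, 2012])
    assert mean == pytest.approx(0.25)
    assert np.isnan(se) and n == 1


def test_site_mean_peak_se_across_polygons():
    peaks = pd.DataFrame(
        {
            "site": "s",
            "polygon_id": [0, 0, 1, 1],
            "year": [2011, 2012] * 2,
            "peak": [0.2, 0.2, 0.4, 0.4],
        }
    )
    mean, se, n = site_mean_peak(peaks, [2011, 2012])
    assert mean == pytest.approx(0.3)
    assert n == 2
    assert se == pytest.approx(np.std([0.2, 0.4], ddof=1) / np.sqrt(2))


def test_published_site_means():
    df = load_site_summary()
    assert df["ndvi_before"].mean() == pytest.approx(0.217, abs=5e-4)
    assert df["ndvi_after"].mean() == pytest.approx(0.325, abs=5e-4)


@pytest.mark.parametrize(
    "before,after,expected",
    [(0.185, 0.335, 81.1), (0.202, 0.262, 29.7), (0.3, 0.3, 0.0)],
)
def test_percent_difference_cases(before, after, expected):
    assert percent_difference(before, after) == pytest.approx(expected, abs=0.05)


def test_percent_difference_properties():
    assert percent_difference(0.2, 0.3) > 0 > percent_difference(0.3, 0.2)
    assert percent_difference(0.2, 0.3) == pytest.approx(percent_difference(2.0, 3.0))
    with pytest.raises(ZeroDivisionError):
        percent_difference(0.0, 0.3)


class TestTTest:
    def test_identical_samples_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = prepost_ttest([0.3, 0.3], [0.3, 0.3])
        assert t == 0.0 and p == 1.0

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(0)
        before = 0.0 + rng.normal(0, 1e-4, 4)
        after = 1.0 + rng.normal(0, 1e-4, 4)
        _, p = prepost_ttest(before, after)
        assert p < 0.001

    def test_matches_closed_form_welch(self):
        before, after = [1.0, 2.0], [3.0, 4.0]
        t, p = prepost_ttest(before, after)
        # hand Welch: t = (3.5-1.5)/sqrt(0.5/2 + 0.5/2), df = 2
        t_hand = 2.0 / np.sqrt(0.5)
        df = 2.0
        p_hand = 2.0 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            prepost_ttest([0.1], [0.2, 0.3])


class TestRainfallOps:
    def test_uniform_pentads_calendar_oracle(self):
        rain = make_rain({2015: 72.0})  # 1 mm per pentad
        total = seasonal_rain_total(rain, [2015], months=(6, 8))
        assert total == pytest.approx(18.0)  # 3 months x 6 pentads x 1 mm

    def test_zero_rain(self):
        rain = make_rain({2015: 0.0})
        assert seasonal_rain_total(rain, [2015]) == 0.0

    def test_missing_pentads_drop_year_with_warning(self):
        rain = make_rain({2015: 72.0, 2016: 72.0})
        rain.pentads = rain.pentads.iloc[:-40]  # truncate 2016
        with pytest.warns(UserWarning, match="dropped"):
            total = seasonal_rain_total(rain, [2015, 2016])
        assert total == pytest.approx(18.0)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            seasonal_rain_total(rain, [2016])

    @pytest.mark.parametrize(
        "total,expected", [(450.0, 0.0), (630.0, 2.571), (270.0, -2.571)]
    )
    def test_standardized_anomaly(self, total, expected):
        rain = make_rain({2015: total})
        assert rainfall_anomaly(rain, 2015) == pytest.approx(expected, abs=5e-3)

    def test_anomaly_zero_sd_rejected(self):
        rain = make_rain({2015: 450.0}, sd=0.0)
        with pytest.raises(ZeroDivisionError):
            rainfall_anomaly(rain, 2015)


class TestRegression:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = ndvi_rain_regression(x, 0.1 * x + 0.05)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.1)

    def test_published_r_squared(self):
        df = load_site_summary()
        before = ndvi_rain_regression(df["rain_before"], df["ndvi_before"])
        after = ndvi_rain_regression(df["rain_after"], df["ndvi_after"])
        assert round(before.r_squared, 2) == 0.24
        assert round(after.r_squared, 2) == 0.15

    def test_r2_equals_squared_pearson_and_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(250, 450, 20)
        y = 0.001 * x + rng.normal(0, 0.05, 20)
        fit = ndvi_rain_regression(x, y)
        assert fit.r_squared == pytest.approx(stats.pearsonr(x, y)[0] ** 2)
        rescaled = ndvi_rain_regression(3.0 * x - 100.0, -2.0 * y + 5.0)
        assert rescaled.r_squared == pytest.approx(fit.r_squared)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            ndvi_rain_regression([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            ndvi_rain_regression([1.0, 2.0], [0.1, 0.2])


def test_summary_table_reproduces_printed_cells():
    """Sign-preserving percent differences match the printed table within
    rounding of the 3-decimal NDVI inputs; the one exception is the
    rainfall cell of the site whose rainfall decreased, printed unsigned
    in the source."""
    df = load_site_summary()
    table = summarize_site_table(
        df[["site", "ndvi_before", "ndvi_after", "rain_before", "rain_after"]]
    )
    sites = table[table["site"] != "Mean"].reset_index(drop=True)
    assert np.abs(sites["ndvi_pct_diff"] - df["ndvi_pct_diff_printed"]).max() <= 0.15
    rain_err = np.abs(sites["rain_pct_diff"].abs() - df["rain_pct_diff_printed"])
    assert rain_err.max() <= 0.4  # integer-mm inputs round coarser
    decreased = sites[sites["rain_pct_diff"] < 0]
    assert list(decreased["site"]) == ["Elkokia"]


def test_synthetic_percent_diff_recovers_effect():
    """With a constant-rainfall synthetic study, the site table's mean NDVI
    percent difference approximates 100*effect/baseline-peak and the
    rainfall percent difference vanishes."""
    cfg = hm.SimulationConfig(
        grid_shape=(64, 64), n_sites=2, polygons_per_site=2,
        rainfall_sd=0.0, cloud_prob=0.1, noise_sd=0.02, seed=21,
    )
    ds = hm.simulate_dataset(cfg)
    series = hm.zonal_aggregate(ds.stack, ds.polygons, mask_flags=(1,))
    peaks = hm.annual_peak(series)
    from halfmoon.prepost import build_site_table

    table = build_site_table(peaks, ds.polygons, ds.rainfall, cfg.start_year, cfg.end_year)
    mean_row = table[table["site"] == "Mean"].iloc[0]
    expected = 100.0 * cfg.effect_size / mean_row["ndvi_before"]
    assert mean_row["ndvi_pct_diff"] == pytest.approx(expected, rel=0.15)
    assert mean_row["rain_pct_diff"] == pytest.approx(0.0, abs=1e-9)
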