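"""Before/after intervention comparison: peak NDVI, rainfall, tests.

This module reproduces the site-level summary table of the analysis: mean
annual peak NDVI before and after each site's intervention, the seasonal
(Jun-Aug) rainfall totals for the same year sets, sign-preserving percent
differences, a two-tailed Welch t-test on the annual peak samples, the
NDVI~rainfall OLS relationship, and standardized rainfall anomalies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rainfall import RainfallSeries, date_parts
from .raster import InterventionPolygon


class ExcludedPolygonError(ValueError):
    """Polygon cannot enter the pre/post analysis (e.g. intervened in the
    final study year, leaving no post-intervention sample)."""


def split_pre_post(
    intervention_year: int, start_year: int, end_year: int
) -> tuple[list[int], list[int]]:
    """Year sets before/after an intervention.

    The intervention year itself belongs to neither period (construction
    happens mid-year and would contaminate either side). A polygon
    intervened in the final study year has no after-period and is excluded.
    """
    if not start_year <= intervention_year <= end_year:
        raise ValueError(
            f"intervention year {intervention_year} outside study span "
            f"{start_year}-{end_year}"
        )
    if intervention_year >= end_year:
        raise ExcludedPolygonError(
            f"polygon intervened in {intervention_year}: no post-intervention "
            "years inside the study span"
        )
    before = list(range(start_year, intervention_year))
    after = list(range(intervention_year + 1, end_year + 1))
    return before, after


def site_mean_peak(
    peaks: pd.DataFrame, years: Iterable[int]
) -> tuple[float, float, int]:
    """Mean annual peak over a site's polygon-years, with the standard
    error across polygons (polygons weighted equally, not by area).

    ``peaks`` must carry columns ``polygon_id, year, peak`` for one site.
    Returns ``(mean, se, n_polygons)``; ``se`` is NaN for a single polygon.
    """
    years = set(years)
    sel = peaks[peaks["year"].isin(years)]
    if sel.empty:
        raise ValueError("no polygon-years in selection")
    mean = float(sel["peak"].mean())
    per_poly = sel.groupby("polygon_id")["peak"].mean()
    n_poly = len(per_poly)
    se = float(per_poly.std(ddof=1) / np.sqrt(n_poly)) if n_poly > 1 else float("nan")
    return mean, se, n_poly


def percent_difference(before: float, after: float) -> float:
    """Sign-preserving percent change, 100 x (after - before) / before."""
    if before == 0:
        raise ZeroDivisionError("percent difference undefined for before == 0")
    return 100.0 * (after - before) / before


def prepost_ttest(
    before: Sequence[float], after: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample two-tailed t-test (Welch by default) on annual peaks."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size < 2 or after.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(before) == 0 and np.ptp(after) == 0 and before[0] == after[0]:
        warnings.warn("degenerate identical samples; p set to 1", stacklevel=2)
        return 0.0, 1.0
    res = stats.ttest_ind(after, before, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def seasonal_rain_total(
    rain: RainfallSeries,
    years: Iterable[int],
    months: tuple[int, int] = (6, 8),
) -> float:
    """Mean over years of the seasonal (default Jun-Aug) pentad sum.

    Years whose seasonal pentad record is incomplete (fewer than the six
    pentads per month the calendar expects) are dropped with a warning.
    """
    lo, hi = months
    years = sorted(set(years))
    df = rain.pentads
    yr, mo = date_parts(df["date"])
    expected = 6 * (hi - lo + 1)
    totals = []
    for year in years:
        sel = df[(yr == year) & (mo >= lo) & (mo <= hi)]
        if len(sel) < expected:
            warnings.warn(
                f"year {year}: {len(sel)}/{expected} pentads present; dropped",
                stacklevel=2,
            )
            continue
        totals.append(sel["rainfall_mm"].sum())
    if not totals:
        raise ValueError(f"no complete years among {years}")
    return float(np.mean(totals))


def rainfall_anomaly(rain: RainfallSeries, year: int) -> float:
    """Standardized annual anomaly, (total - long-term mean) / long-term SD."""
    if rain.long_term_sd == 0:
        raise ZeroDivisionError("long-term rainfall SD is zero")
    totals = rain.annual_totals()
    if year not in totals.index:
        raise KeyError(f"year {year} not covered by the rainfall series")
    return float((totals.loc[year] - rain.long_term_mean) / rain.long_term_sd)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with the squared Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def ndvi_rain_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of peak NDVI on seasonal rainfall."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


TABLE1_COLUMNS = [
    "site",
    "ndvi_before",
    "ndvi_after",
    "rain_before",
    "rain_after",
    "ndvi_pct_diff",
    "rain_pct_diff",
    "t_statistic",
    "p_value",
]


def summarize_site_table(site_stats: pd.DataFrame) -> pd.DataFrame:
    """Add percent-difference columns and a grand Mean row to a site table.

    ``site_stats`` needs columns ``site, ndvi_before, ndvi_after,
    rain_before, rain_after`` (and optionally ``t_statistic, p_value``).
    The Mean row is the unweighted mean of the site rows, and its percent
    differences are the means of the per-site percent differences.
    """
    df = site_stats.copy()
    df["ndvi_pct_diff"] = 100.0 * (df["ndvi_after"] - df["ndvi_before"]) / df["ndvi_before"]
    df["rain_pct_diff"] = 100.0 * (df["rain_after"] - df["rain_before"]) / df["rain_before"]
    for col in ("t_statistic", "p_value"):
        if col not in df.columns:
            df[col] = np.nan
    mean_row = {
        "site": "Mean",
        "ndvi_before": df["ndvi_before"].mean(),
        "ndvi_after": df["ndvi_after"].mean(),
        "rain_before": df["rain_before"].mean(),
        "rain_after": df["rain_after"].mean(),
        "ndvi_pct_diff": df["ndvi_pct_diff"].mean(),
        "rain_pct_diff": df["rain_pct_diff"].mean(),
        "t_statistic": np.nan,
        "p_value": np.nan,
    }
    out = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    return out[TABLE1_COLUMNS]


def build_site_table(
    peaks: pd.DataFrame,
    polygons: Sequence[InterventionPolygon],
    rain: RainfallSeries,
    start_year: int,
    end_year: int,
    rain_months: tuple[int, int] = (6, 8),
) -> pd.DataFrame:
    """Full pre/post summary from pipeline outputs.

    For each site: polygon-level annual peaks are split by each polygon's
    own intervention year, site means taken over polygon-years, seasonal
    rainfall averaged over the site's pooled before/after year sets, and a
    Welch t-test run on the pooled before vs after peak samples. Polygons
    intervened in the final study year are excluded.
    """
    rows = []
    for site, site_polys in _group_by_site(polygons):
        before_vals: list[float] = []
        after_vals: list[float] = []
        before_years: set[int] = set()
        after_years: set[int] = set()
        for poly in site_polys:
            try:
                byrs, ayrs = split_pre_post(poly.intervention_year, start_year, end_year)
            except ExcludedPolygonError:
                continue
            ppeaks = peaks[
                (peaks["site"] == site) & (peaks["polygon_id"] == poly.polygon_id)
            ]
            before_vals += list(ppeaks[ppeaks["year"].isin(byrs)]["peak"])
            after_vals += list(ppeaks[ppeaks["year"].isin(ayrs)]["peak"])
            before_years |= set(byrs)
            after_years |= set(ayrs)
        if not before_vals or not after_vals:
            continue
        if len(before_vals) >= 2 and len(after_vals) >= 2:
            t, p = prepost_ttest(before_vals, after_vals)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "site": site,
                "ndvi_before": float(np.mean(before_vals)),
                "ndvi_after": float(np.mean(after_vals)),
                "rain_before": seasonal_rain_total(rain, before_years, rain_months),
                "rain_after": seasonal_rain_total(rain, after_years, rain_months),
                "t_statistic": t,
                "p_value": p,
            }
        )
    if not rows:
        raise ExcludedPolygonError("no analyzable polygons (all excluded)")
    return summarize_site_table(pd.DataFrame(rows))


def _group_by_site(
    polygons: Sequence[InterventionPolygon],
) -> list[tuple[str, list[InterventionPolygon]]]:
    sites: dict[str, list[InterventionPolygon]] = {}
    for p in polygons:
        sites.setdefault(p.site, []).append(p)
    return sorted(sites.items())
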