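"""Monthly composites and annual growing-season peak statistics.

The monthly composite is the arithmetic mean of the scene-level polygon
NDVI values in that calendar month whose valid-pixel fraction clears a
threshold (max-value compositing is deliberately not used: the downstream
comparisons are built on average monthly greenness).

The annual "peak" is a high percentile (default 95th) of the scene-level
polygon-mean NDVI values falling in the peak growing-season window
(default Aug-Oct). Taking the percentile over scene-level polygon means --
rather than pooling pixels -- matches the aggregate-then-analyze order of
the rest of the pipeline; a pixel-pooling variant is available separately.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .raster import InterventionPolygon, SceneStack, apply_qa_mask, compute_ndvi, polygon_pixel_mask

MONTHLY_COLUMNS = ["site", "polygon_id", "year", "month", "ndvi", "n_obs", "n_expected", "availability"]


def monthly_composite(
    series: pd.DataFrame, min_valid_fraction: float = 0.5
) -> pd.DataFrame:
    """Collapse a scene-level polygon series to calendar months.

    Parameters
    ----------
    series
        Scene-level polygon series (columns ``site, polygon_id, date,
        ndvi_mean, n_valid, valid_fraction``).
    min_valid_fraction
        Scenes with a smaller fraction of valid (clear, in-polygon) pixels
        are excluded from the composite.

    Returns a frame with one row per polygon x year x month present in the
    input: composite NDVI (NaN when no scene qualifies -- never zero),
    ``n_obs`` qualifying scenes, ``n_expected`` acquired scenes and their
    ratio ``availability``.
    """
    if series.empty:
        return pd.DataFrame(columns=MONTHLY_COLUMNS)
    df = series.copy()
    ts = pd.to_datetime(df["date"])
    df["year"] = ts.dt.year
    df["month"] = ts.dt.month
    ok = (df["valid_fraction"] >= min_valid_fraction) & df["ndvi_mean"].notna()
    df["_ndvi_ok"] = df["ndvi_mean"].where(ok)
    grouped = df.groupby(["site", "polygon_id", "year", "month"], sort=True)
    out = grouped.agg(
        ndvi=("_ndvi_ok", "mean"),
        n_obs=("_ndvi_ok", "count"),
        n_expected=("date", "count"),
    ).reset_index()
    out["availability"] = out["n_obs"] / out["n_expected"]
    return out[MONTHLY_COLUMNS]


def annual_peak(
    series: pd.DataFrame,
    window: tuple[int, int] = (8, 10),
    q: float = 95.0,
    min_valid_fraction: float = 0.5,
) -> pd.DataFrame:
    """Annual peak NDVI: the q-th percentile (linear interpolation between
    order statistics) of scene-level polygon NDVI inside the window.

    Returns one row per polygon x year with a non-missing window value:
    ``site, polygon_id, year, peak, n_obs``.
    """
    if not 0.0 < q <= 100.0:
        raise ValueError(f"percentile q={q} outside (0, 100]")
    lo, hi = window
    if series.empty:
        return pd.DataFrame(columns=["site", "polygon_id", "year", "peak", "n_obs"])
    df = series.copy()
    ts = pd.to_datetime(df["date"])
    df["year"] = ts.dt.year
    df["month"] = ts.dt.month
    df = df[
        (df["month"] >= lo)
        & (df["month"] <= hi)
        & (df["valid_fraction"] >= min_valid_fraction)
        & df["ndvi_mean"].notna()
    ]
    if df.empty:
        return pd.DataFrame(columns=["site", "polygon_id", "year", "peak", "n_obs"])
    out = (
        df.groupby(["site", "polygon_id", "year"], sort=True)["ndvi_mean"]
        .agg(peak=lambda v: float(np.percentile(v, q)), n_obs="count")
        .reset_index()
    )
    return out


def annual_peak_pixelpool(
    stack: SceneStack,
    polygons: Sequence[InterventionPolygon],
    window: tuple[int, int] = (8, 10),
    q: float = 95.0,
    mask_flags: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Alternative peak statistic pooling all valid pixel NDVI values of the
    window scenes (pixels x scenes) before taking the percentile."""
    if not 0.0 < q <= 100.0:
        raise ValueError(f"percentile q={q} outside (0, 100]")
    lo, hi = window
    ndvi = apply_qa_mask(compute_ndvi(stack.red, stack.nir), stack.qa, mask_flags)
    years = sorted({d.year for d in stack.dates})
    records = []
    for poly in polygons:
        pmask = polygon_pixel_mask(poly.geometry, stack.transform, stack.grid_shape)
        if not pmask.any():
            continue
        for year in years:
            sel = [i for i, d in enumerate(stack.dates) if d.year == year and lo <= d.month <= hi]
            vals = ndvi[sel][:, pmask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            records.append(
                {
                    "site": poly.site,
                    "polygon_id": poly.polygon_id,
                    "year": year,
                    "peak": float(np.percentile(vals, q)),
                    "n_obs": int(vals.size),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["site", "polygon_id", "year", "peak", "n_obs"]
    )


def availability_report(
    monthly: pd.DataFrame, window: tuple[int, int] = (8, 10)
) -> tuple[pd.DataFrame, dict]:
    """Scene availability inside the window, per polygon-year.

    Availability is the fraction of acquired scenes that survived QA/valid-
    fraction screening. Returns the per-polygon-year table plus a summary
    with the minimum and mean.
    """
    lo, hi = window
    if monthly.empty:
        return (
            pd.DataFrame(columns=["site", "polygon_id", "year", "n_obs", "n_expected", "availability"]),
            {"min": np.nan, "mean": np.nan},
        )
    df = monthly[(monthly["month"] >= lo) & (monthly["month"] <= hi)]
    out = (
        df.groupby(["site", "polygon_id", "year"], sort=True)[["n_obs", "n_expected"]]
        .sum()
        .reset_index()
    )
    out["availability"] = out["n_obs"] / out["n_expected"]
    summary = {
        "min": float(out["availability"].min()) if len(out) else np.nan,
        "mean": float(out["availability"].mean()) if len(out) else np.nan,
    }
    return out, summary
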