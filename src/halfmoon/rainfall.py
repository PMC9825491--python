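"""Pentad rainfall series: calendar helpers, containers, disk format.

CHIRPS-style convention: six pentads per month starting on days 1, 6, 11,
16, 21 and 26; the sixth pentad absorbs the remainder of the month, giving
72 pentads per year.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

PENTAD_START_DAYS = (1, 6, 11, 16, 21, 26)


def date_parts(dates: pd.Series) -> tuple[pd.Series, pd.Series]:
    """(year, month) Series for a column of dates.

    Works on date objects, timestamps or ISO strings without going through
    nanosecond datetimes, so multi-millennium simulated records are fine.
    """

    def _parse(v):
        if isinstance(v, str):
            v = dt.date.fromisoformat(v[:10])
        return v.year, v.month

    parts = dates.map(_parse)
    years = parts.map(lambda t: t[0])
    months = parts.map(lambda t: t[1])
    return years, months


def pentad_starts(year: int) -> list[dt.date]:
    """The 72 pentad start dates of a calendar year."""
    return [
        dt.date(year, month, day)
        for month in range(1, 13)
        for day in PENTAD_START_DAYS
    ]


@dataclass
class RainfallSeries:
    """Areal rainfall at pentad resolution plus its long-term climatology.

    ``pentads`` has columns ``date`` (pentad start) and ``rainfall_mm``.
    ``long_term_mean``/``long_term_sd`` are the annual-total statistics of
    the reference climatology used for standardized anomalies.
    """

    pentads: pd.DataFrame
    long_term_mean: float
    long_term_sd: float

    def __post_init__(self) -> None:
        if (self.pentads["rainfall_mm"] < 0).any():
            raise ValueError("rainfall must be non-negative")

    def annual_totals(self) -> pd.Series:
        df = self.pentads
        years, _ = date_parts(df["date"])
        out = df.groupby(years)["rainfall_mm"].sum().rename("rainfall_mm")
        out.index.name = "date"
        return out

    def monthly_totals(self) -> pd.DataFrame:
        df = self.pentads
        years, months = date_parts(df["date"])
        return (
            df.groupby([years.rename("year"), months.rename("month")])["rainfall_mm"]
            .sum()
            .reset_index()
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.pentads.to_csv(path, index=False)
        return path


def write_rainfall_grids(
    series: RainfallSeries,
    out_dir: str | Path,
    grid_shape: tuple[int, int] = (8, 8),
    transform: tuple[float, ...] = (500_000.0, 5000.0, 0.0, 1_500_000.0, 0.0, -5000.0),
    crs: str = "EPSG:32632",
) -> list[Path]:
    """Write one (spatially uniform) rainfall grid TIFF per pentad."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for _, row in series.pentads.iterrows():
        date = pd.Timestamp(row["date"]).date()
        grid = np.full(grid_shape, float(row["rainfall_mm"]), dtype=np.float32)
        meta = {
            "date": date.isoformat(),
            "transform": list(transform),
            "crs": crs,
            "long_term_mean": series.long_term_mean,
            "long_term_sd": series.long_term_sd,
        }
        p = out_dir / f"rain_{date.strftime('%Y%m%d')}.tif"
        tifffile.imwrite(p, grid, description=json.dumps(meta))
        paths.append(p)
    return paths


def read_rainfall_grids(
    rain_dir: str | Path, x: float | None = None, y: float | None = None
) -> RainfallSeries:
    """Rebuild a pentad series by sampling rainfall grids at a point.

    With ``x``/``y`` omitted the grid center is sampled (the synthetic grids
    are spatially uniform, so the choice is immaterial there).
    """
    rain_dir = Path(rain_dir)
    paths = sorted(rain_dir.glob("rain_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no rain_YYYYMMDD.tif files in {rain_dir}")
    records = []
    mean = sd = None
    for p in paths:
        with tifffile.TiffFile(p) as tif:
            grid = tif.asarray()
            meta = json.loads(tif.pages[0].description)
        mean = meta.get("long_term_mean", mean)
        sd = meta.get("long_term_sd", sd)
        x0, dx, _, y0, _, dy = meta["transform"]
        if x is None or y is None:
            row = grid.shape[0] // 2
            col = grid.shape[1] // 2
        else:
            col = int((x - x0) / dx)
            row = int((y - y0) / dy)
        row = int(np.clip(row, 0, grid.shape[0] - 1))
        col = int(np.clip(col, 0, grid.shape[1] - 1))
        records.append(
            {"date": dt.date.fromisoformat(meta["date"]), "rainfall_mm": float(grid[row, col])}
        )
    df = pd.DataFrame.from_records(records).sort_values("date").reset_index(drop=True)
    totals = df.groupby(pd.to_datetime(df["date"]).dt.year)["rainfall_mm"].sum()
    if mean is None:
        mean = float(totals.mean())
    if sd is None:
        sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
    return RainfallSeries(pentads=df, long_term_mean=float(mean), long_term_sd=float(sd))
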