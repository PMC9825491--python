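"""Scene stacks, NDVI, QA masking and polygon zonal aggregation.

Scenes are stored on disk as plain multiband TIFFs (bands: red, NIR, QA)
with the acquisition date encoded in the filename (``scene_YYYYMMDD.tif``)
and a JSON metadata tag carrying the geotransform, CRS identifier and band
order. In memory a :class:`SceneStack` holds the full dated stack on a
common grid.

Conventions: raster rows/cols are 0-based; the geotransform maps the outer
corner of pixel (0, 0); pixels are half-open intervals; a pixel belongs to a
polygon when its center is contained in the polygon.
"""
from __future__ import annotations

import datetime as dt
import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

Transform = tuple[float, float, float, float, float, float]

#: QA flag vocabulary: 0 clear, 1 cloud, 2 cloud shadow, 3 fill/no-data.
QA_CLEAR = 0
QA_CLOUD = 1
QA_SHADOW = 2
QA_FILL = 3
DEFAULT_MASK_FLAGS: frozenset[int] = frozenset({QA_CLOUD, QA_SHADOW, QA_FILL})

_SCENE_RE = re.compile(r"scene_(\d{8})\.tif$")


@dataclass
class InterventionPolygon:
    """A half-moon intervention polygon with its planning metadata."""

    site: str
    polygon_id: int
    geometry: BaseGeometry
    intervention_year: int
    zone: str  # "agricultural" | "pastoral"
    area_ha: float

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"polygon {self.polygon_id}: area_ha must be > 0")
        if not self.geometry.is_valid:
            raise ValueError(f"polygon {self.polygon_id}: invalid geometry")
        if self.zone not in ("agricultural", "pastoral"):
            raise ValueError(f"polygon {self.polygon_id}: unknown zone {self.zone!r}")


@dataclass
class SceneStack:
    """Dated red/NIR/QA layers on one grid.

    ``red``/``nir`` are float32 reflectance in [0, 1] with NaN for missing;
    ``qa`` is uint8 per-pixel flags; all arrays are shaped
    ``(n_scenes, rows, cols)`` and share ``transform``/``crs``.
    """

    dates: list[dt.date]
    red: np.ndarray
    nir: np.ndarray
    qa: np.ndarray
    transform: Transform
    crs: str = "EPSG:32632"

    def __post_init__(self) -> None:
        if not (self.red.shape == self.nir.shape == self.qa.shape):
            raise ValueError("red/nir/qa shapes differ")
        if len(self.dates) != self.red.shape[0]:
            raise ValueError("number of dates != number of scenes")
        if any(b >= a for a, b in zip(self.dates[1:], self.dates[:-1])):
            raise ValueError("acquisition dates must be strictly increasing")

    @property
    def n_scenes(self) -> int:
        return len(self.dates)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.red.shape[1:]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of pixel centers, each shaped like the grid."""
        x0, dx, _, y0, _, dy = self.transform
        rows, cols = self.grid_shape
        xs = x0 + (np.arange(cols) + 0.5) * dx
        ys = y0 + (np.arange(rows) + 0.5) * dy
        return np.meshgrid(xs, ys)


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """Normalized Difference Vegetation Index, (NIR - Red)/(NIR + Red).

    Pixels where the denominator is zero (or an input is missing) come back
    as NaN. Negative reflectance is rejected: surface reflectance products
    are non-negative and a negative value signals a scaling error upstream.
    """
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if red.shape != nir.shape:
        raise ValueError(f"shape mismatch: red {red.shape} vs nir {nir.shape}")
    if np.nanmin(red, initial=0.0) < 0 or np.nanmin(nir, initial=0.0) < 0:
        raise ValueError("reflectance must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, np.nan)
    return ndvi


def apply_qa_mask(
    ndvi: np.ndarray,
    qa: np.ndarray,
    mask_flags: Iterable[int] = DEFAULT_MASK_FLAGS,
    clear_flags: Iterable[int] = (QA_CLEAR,),
) -> np.ndarray:
    """Set NDVI to NaN wherever the QA flag is in ``mask_flags``.

    Flags that are neither clear nor listed for masking are unknown; they
    are masked conservatively with a warning.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    qa = np.asarray(qa)
    if ndvi.shape != qa.shape:
        raise ValueError(f"shape mismatch: ndvi {ndvi.shape} vs qa {qa.shape}")
    mask_flags = frozenset(int(f) for f in mask_flags)
    clear = frozenset(int(f) for f in clear_flags)
    unknown = np.setdiff1d(np.unique(qa), sorted(mask_flags | clear))
    if unknown.size:
        warnings.warn(
            f"unknown QA flag values {unknown.tolist()} treated as masked",
            stacklevel=2,
        )
    drop = np.isin(qa, sorted(mask_flags)) | np.isin(qa, unknown)
    return np.where(drop, np.nan, ndvi)


def polygon_pixel_mask(
    polygon: BaseGeometry,
    transform: Transform,
    grid_shape: tuple[int, int],
) -> np.ndarray:
    """Boolean grid of pixels whose centers fall inside the polygon."""
    x0, dx, _, y0, _, dy = transform
    rows, cols = grid_shape
    xs = x0 + (np.arange(cols) + 0.5) * dx
    ys = y0 + (np.arange(rows) + 0.5) * dy
    xx, yy = np.meshgrid(xs, ys)
    return shapely.contains_xy(polygon, xx, yy)


def zonal_aggregate(
    stack: SceneStack,
    polygons: Sequence[InterventionPolygon],
    mask_flags: Iterable[int] = DEFAULT_MASK_FLAGS,
) -> pd.DataFrame:
    """Per-polygon, per-date mean NDVI over valid (clear, in-polygon) pixels.

    Returns the pipeline's central time series: one row per polygon x scene
    with columns ``site, polygon_id, date, ndvi_mean, n_valid,
    valid_fraction``. ``ndvi_mean`` is NaN when no valid pixel remains --
    never silently zero. A polygon with no pixel center inside the raster
    extent is flagged with a warning and contributes no rows.
    """
    ndvi = compute_ndvi(stack.red, stack.nir)
    ndvi = apply_qa_mask(ndvi, stack.qa, mask_flags=mask_flags)
    records: list[dict] = []
    for poly in polygons:
        pmask = polygon_pixel_mask(poly.geometry, stack.transform, stack.grid_shape)
        n_pixels = int(pmask.sum())
        if n_pixels == 0:
            warnings.warn(
                f"polygon {poly.polygon_id} ({poly.site}) outside raster extent; "
                "empty series",
                stacklevel=2,
            )
            continue
        vals = ndvi[:, pmask]  # (n_scenes, n_pixels)
        valid = np.isfinite(vals)
        n_valid = valid.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(vals, axis=1)
        means = np.where(n_valid > 0, means, np.nan)
        for i, date in enumerate(stack.dates):
            records.append(
                {
                    "site": poly.site,
                    "polygon_id": poly.polygon_id,
                    "date": date,
                    "ndvi_mean": means[i],
                    "n_valid": int(n_valid[i]),
                    "valid_fraction": n_valid[i] / n_pixels,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["site", "polygon_id", "date", "ndvi_mean", "n_valid", "valid_fraction"],
    )


# ---------------------------------------------------------------------------
# disk formats


def write_scene(
    path: str | Path,
    date: dt.date,
    red: np.ndarray,
    nir: np.ndarray,
    qa: np.ndarray,
    transform: Transform,
    crs: str,
) -> Path:
    """Write one scene as a 3-band TIFF (red, NIR, QA) with JSON metadata."""
    path = Path(path)
    meta = {
        "date": date.isoformat(),
        "transform": list(transform),
        "crs": crs,
        "bands": ["red", "nir", "qa"],
    }
    data = np.stack(
        [red.astype(np.float32), nir.astype(np.float32), qa.astype(np.float32)]
    )
    tifffile.imwrite(
        path, data, photometric="minisblack", planarconfig="separate",
        description=json.dumps(meta),
    )
    return path


def scene_filename(date: dt.date) -> str:
    return f"scene_{date.strftime('%Y%m%d')}.tif"


def write_scene_stack(stack: SceneStack, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, date in enumerate(stack.dates):
        paths.append(
            write_scene(
                out_dir / scene_filename(date),
                date,
                stack.red[i],
                stack.nir[i],
                stack.qa[i],
                stack.transform,
                stack.crs,
            )
        )
    return paths


def read_scene_stack(scenes_dir: str | Path) -> SceneStack:
    """Read every ``scene_YYYYMMDD.tif`` under ``scenes_dir`` into a stack."""
    scenes_dir = Path(scenes_dir)
    paths = sorted(p for p in scenes_dir.glob("scene_*.tif") if _SCENE_RE.search(p.name))
    if not paths:
        raise FileNotFoundError(f"no scene_YYYYMMDD.tif files in {scenes_dir}")
    dates, reds, nirs, qas = [], [], [], []
    transform: Transform | None = None
    crs = "unknown"
    for p in paths:
        m = _SCENE_RE.search(p.name)
        assert m is not None
        dates.append(dt.datetime.strptime(m.group(1), "%Y%m%d").date())
        with tifffile.TiffFile(p) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        if desc:
            meta = json.loads(desc)
            transform = tuple(meta["transform"])  # type: ignore[assignment]
            crs = meta.get("crs", crs)
        reds.append(data[0])
        nirs.append(data[1])
        qas.append(data[2].astype(np.uint8))
    if transform is None:
        raise ValueError("scenes carry no geotransform metadata")
    return SceneStack(
        dates=dates,
        red=np.stack(reds),
        nir=np.stack(nirs),
        qa=np.stack(qas),
        transform=transform,
        crs=crs,
    )


def write_polygons(
    polygons: Sequence[InterventionPolygon], path: str | Path, crs: str = "EPSG:32632"
) -> Path:
    """Write intervention polygons as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {
                "site": p.site,
                "polygon_id": p.polygon_id,
                "year": p.intervention_year,
                "zone": p.zone,
                "area_ha": p.area_ha,
            },
        }
        for p in polygons
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_polygons(path: str | Path) -> list[InterventionPolygon]:
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc["features"]:
        props = feat["properties"]
        out.append(
            InterventionPolygon(
                site=props["site"],
                polygon_id=int(props["polygon_id"]),
                geometry=shape(feat["geometry"]),
                intervention_year=int(props["year"]),
                zone=props["zone"],
                area_ha=float(props["area_ha"]),
            )
        )
    return out


def write_polygon_series(series: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    series.to_csv(path, index=False)
    return path
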