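"""End-to-end pipeline: ingest -> time series -> pre/post -> pairs -> BACI.

A run writes a self-describing directory: the site summary table, the pair
table, the BACI JSON, a log with per-stage record counts, and a snapshot of
the configuration that produced it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import baci as baci_mod
from . import pairing, prepost, synthetic, timeseries
from .config import PipelineConfig
from .rainfall import read_rainfall_grids
from .raster import read_polygons, read_scene_stack, zonal_aggregate

log = logging.getLogger("halfmoon")


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check input files/metadata; every failure is listed, none raised."""
    report = ValidationReport()
    if config.synthetic:
        return report
    if not config.scenes_dir or not Path(config.scenes_dir).is_dir():
        report.failures.append(f"scenes_dir missing: {config.scenes_dir}")
    if not config.polygons_path or not Path(config.polygons_path).is_file():
        report.failures.append(f"polygons_path missing: {config.polygons_path}")
    if not config.rainfall_dir or not Path(config.rainfall_dir).is_dir():
        report.failures.append(f"rainfall_dir missing: {config.rainfall_dir}")
    if report.failures:
        return report
    import re

    for p in sorted(Path(config.scenes_dir).glob("*.tif")):
        if not re.match(r"scene_\d{8}\.tif$", p.name):
            report.failures.append(f"unparsable scene filename: {p.name}")
    try:
        stack = read_scene_stack(config.scenes_dir)
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        report.failures.append(f"scene stack unreadable: {exc}")
        stack = None
    polygons = []
    try:
        polygons = read_polygons(config.polygons_path)
        if not polygons:
            report.failures.append("empty polygon set")
        for p in polygons:
            if not p.geometry.is_valid:
                report.failures.append(f"invalid geometry: polygon {p.polygon_id}")
    except KeyError as exc:
        report.failures.append(f"polygon property missing: {exc}")
    except Exception as exc:  # noqa: BLE001
        report.failures.append(f"polygons unreadable: {exc}")
        polygons = []
    if stack is not None and polygons:
        doc_crs = _geojson_crs(config.polygons_path)
        if doc_crs and doc_crs != stack.crs:
            report.failures.append(
                f"CRS mismatch: scenes {stack.crs} vs polygons {doc_crs}"
            )
    return report


def _geojson_crs(path: str | Path) -> str | None:
    import json

    doc = json.loads(Path(path).read_text())
    return doc.get("crs", {}).get("properties", {}).get("name")


@dataclass
class PipelineResult:
    site_table: pd.DataFrame
    pair_table: pd.DataFrame
    baci: baci_mod.BACIResult | None
    regression_before: prepost.RegressionFit | None
    regression_after: prepost.RegressionFit | None
    peaks: pd.DataFrame
    monthly: pd.DataFrame
    output_dir: Path | None


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis per the configuration.

    With ``config.synthetic`` the simulated dataset is generated in memory;
    otherwise scenes/polygons/rainfall are read from the configured paths.
    """
    out_dir = Path(config.output_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        return _run(config, out_dir if write else None)
    finally:
        if write:
            log.removeHandler(handler)
            handler.close()


def _run(config: PipelineConfig, out_dir: Path | None) -> PipelineResult:
    if config.synthetic:
        sim = config.simulation
        ds = synthetic.simulate_dataset(sim)
        stack, polygons, rain = ds.stack, ds.polygons, ds.rainfall
        start_year, end_year = sim.start_year, sim.end_year
    else:
        report = validate_inputs(config)
        if not report.ok:
            raise FileNotFoundError("; ".join(report.failures))
        stack = read_scene_stack(config.scenes_dir)
        polygons = read_polygons(config.polygons_path)
        rain = read_rainfall_grids(config.rainfall_dir)
        start_year, end_year = config.start_year, config.end_year
    log.info("scenes read: %d (%s..%s)", stack.n_scenes, stack.dates[0], stack.dates[-1])
    log.info("polygons: %d across %d sites", len(polygons), len({p.site for p in polygons}))

    series = zonal_aggregate(stack, polygons, mask_flags=config.mask_flags)
    masked_px = int((series["n_valid"] == 0).sum())
    log.info("polygon-scene records: %d (fully-masked records: %d)", len(series), masked_px)

    monthly = timeseries.monthly_composite(series, config.min_valid_fraction)
    peaks = timeseries.annual_peak(
        series, window=config.peak_window, q=config.peak_q,
        min_valid_fraction=config.min_valid_fraction,
    )
    log.info("monthly composites: %d; polygon-year peaks: %d", len(monthly), len(peaks))

    site_table = prepost.build_site_table(
        peaks, polygons, rain, start_year, end_year, rain_months=config.rain_window
    )
    n_sites_analyzed = len(site_table) - 1  # minus Mean row
    log.info("sites analyzed pre/post: %d", n_sites_analyzed)

    sites_only = site_table[site_table["site"] != "Mean"]
    reg_before = reg_after = None
    if len(sites_only) >= 3:
        try:
            reg_before = prepost.ndvi_rain_regression(
                sites_only["rain_before"], sites_only["ndvi_before"]
            )
            reg_after = prepost.ndvi_rain_regression(
                sites_only["rain_after"], sites_only["ndvi_after"]
            )
        except ValueError as exc:
            # e.g. spatially uniform rainfall: all sites share one series
            log.warning("NDVI~rain regression skipped: %s", exc)

    pairs = pairing.select_pairs(
        polygons,
        min_gap_years=config.min_gap_years,
        min_area_ha=config.min_area_ha,
        start_year=start_year,
    )
    log.info("control/experiment pairs selected: %d", len(pairs))
    summaries = []
    for pair in pairs:
        try:
            summaries.append(pairing.pair_period_means(pair, monthly))
        except ValueError as exc:
            log.warning("pair %s dropped: %s", pair.site, exc)
    pair_table = (
        pairing.summaries_to_frame(summaries) if summaries else pd.DataFrame()
    )

    result_baci = None
    if len(summaries) >= 2:
        result_baci = baci_mod.bootstrap_baci(
            summaries, n_iterations=config.bootstrap_iterations, seed=config.seed
        )
        log.info(
            "BACI contrast %.4f (relative %.3f), %d bootstrap iterations",
            result_baci.contrast, result_baci.relative_contrast,
            result_baci.n_iterations,
        )

    if out_dir is not None:
        config.to_yaml(str(out_dir / "config.yaml"))
        _write_csv(site_table, out_dir / "table1.csv")
        _write_csv(pair_table, out_dir / "table2.csv")
        if result_baci is not None:
            result_baci.to_json(out_dir / "baci.json")
        _write_csv(peaks, out_dir / "annual_peaks.csv")
        _write_csv(monthly, out_dir / "monthly_composites.csv")
        log.info("outputs written to %s", out_dir)

    return PipelineResult(
        site_table=site_table,
        pair_table=pair_table,
        baci=result_baci,
        regression_before=reg_before,
        regression_after=reg_after,
        peaks=peaks,
        monthly=monthly,
        output_dir=out_dir,
    )


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
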