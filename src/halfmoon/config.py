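"""Configuration objects for simulation and pipeline runs.

All randomness in the package flows from a single integer seed; substreams
for independent components (rainfall, clouds, NDVI noise) are spawned with
:func:`numpy.random.default_rng` seeded by ``[seed, stream]`` so that adding
a component never perturbs another component's draws.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

#: months in which the intervention effect is active (construction retains
#: rain-season water, so greening shows from the rains into the dry-down).
GROWING_SEASON_MONTHS: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12)

#: long-term monthly rainfall climatology (fraction of the annual total per
#: calendar month) for a Sahelian unimodal Jun-Sept regime; Jun-Sept carries
#: 92% of the annual total.
MONTHLY_RAIN_FRACTIONS: tuple[float, ...] = (
    0.0, 0.0, 0.0, 0.005, 0.025, 0.12, 0.27, 0.33, 0.20, 0.04, 0.007, 0.003
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic Landsat-like scene/rainfall generator.

    Defaults emulate the study conditions: an 11-year record (2010-2020) of
    16-day-revisit 30 m reflectance over a small Sahelian domain with a
    Jun-Sept rainy season, NDVI peaking around 1 September, rainfall-coupled
    interannual variability, independent per-pixel cloud gaps, and a step
    increase in growing-season greenness inside intervened polygons.
    """

    start_year: int = 2010
    end_year: int = 2020
    revisit_days: int = 16
    grid_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 30.0
    n_sites: int = 4
    polygons_per_site: int = 3
    #: polygon_id -> intervention year; None assigns the default rotation
    #: (2013, 2015, 2018, ...) within each site, which guarantees that every
    #: site contains at least one >=3-year-gap control/experiment pair.
    intervention_years: Mapping[int, int] | None = None
    effect_size: float = 0.10
    seasonal_amplitude: float = 0.22
    baseline_ndvi: float = 0.12
    rainfall_mean: float = 450.0
    rainfall_sd: float = 70.0
    rain_coupling: float = 3.0e-4  # NDVI units per mm of annual-rain anomaly
    cloud_prob: float = 0.26
    noise_sd: float = 0.02
    seed: int = 0
    crs: str = "EPSG:32632"
    origin: tuple[float, float] = (500_000.0, 1_500_000.0)

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if self.revisit_days < 1:
            raise ValueError("revisit_days must be >= 1")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.rainfall_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.intervention_years is not None:
            for pid, year in self.intervention_years.items():
                if not self.start_year <= year <= self.end_year:
                    raise ValueError(
                        f"intervention year {year} for polygon {pid} outside "
                        f"study span {self.start_year}-{self.end_year}"
                    )
        # Deterministic NDVI component must stay inside the physical range.
        # Worst cases: peak season + effect + a +4 sigma rain year, and
        # trough season with a -4 sigma rain year.
        swing = self.rain_coupling * 4.0 * self.rainfall_sd
        hi = self.baseline_ndvi + self.seasonal_amplitude + self.effect_size + swing
        lo = self.baseline_ndvi - swing
        if hi > 1.0 or lo < -1.0:
            raise ValueError(
                f"deterministic NDVI range [{lo:.3f}, {hi:.3f}] leaves [-1, 1]; "
                "reduce baseline_ndvi/seasonal_amplitude/effect_size/rain_coupling"
            )

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def transform(self) -> tuple[float, float, float, float, float, float]:
        """GDAL-style geotransform (x0, dx, 0, y0, 0, -dy), north-up."""
        x0, y0 = self.origin
        return (x0, self.pixel_size, 0.0, y0, 0.0, -self.pixel_size)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; serializable to/from YAML."""

    scenes_dir: str | None = None
    polygons_path: str | None = None
    rainfall_dir: str | None = None
    synthetic: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    start_year: int = 2010
    end_year: int = 2020
    peak_window: tuple[int, int] = (8, 10)
    peak_q: float = 95.0
    rain_window: tuple[int, int] = (6, 8)
    mask_flags: tuple[int, ...] = (1, 2)
    min_valid_fraction: float = 0.5
    min_gap_years: int = 3
    min_area_ha: float = 13.0
    bootstrap_iterations: int = 50
    seed: int = 0
    output_dir: str = "run_output"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if isinstance(sim, dict):
            sim = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            }
            if isinstance(sim.get("intervention_years"), dict):
                sim["intervention_years"] = {
                    int(k): int(v) for k, v in sim["intervention_years"].items()
                }
            d["simulation"] = SimulationConfig(**sim)
        for key in ("peak_window", "rain_window", "mask_flags"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        def _plain(obj):
            if isinstance(obj, tuple):
                return [_plain(x) for x in obj]
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_plain(x) for x in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
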