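"""Rule-based control/experiment polygon pairing.

No control sites were designated at planning time, so pairs are formed
retrospectively from polygons of the same site that were intervened years
apart: the earlier-intervened polygon is the experiment member and the
later-intervened one serves as control until its own intervention. Three
criteria gate a pair: same site, same livelihood zone, intervention years
at least ``min_gap_years`` apart; both members must also clear a minimum
area so polygon-mean NDVI rests on a substantial pixel count.

Periods (year-level granularity): baseline runs from the study start
through the experiment member's intervention year; the experiment period
from the following year through the control member's intervention year;
later years (both members intervened) are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .raster import InterventionPolygon


@dataclass(frozen=True)
class ControlPair:
    site: str
    experiment: InterventionPolygon
    control: InterventionPolygon
    baseline_years: tuple[int, int]  # inclusive range
    experiment_years: tuple[int, int]  # inclusive range

    def __post_init__(self) -> None:
        if self.experiment.site != self.control.site:
            raise ValueError("pair members must share a site")
        if self.experiment.zone != self.control.zone:
            raise ValueError("pair members must share a livelihood zone")
        gap = self.control.intervention_year - self.experiment.intervention_year
        if gap < 3:
            raise ValueError(f"intervention gap {gap} < 3 years")


@dataclass(frozen=True)
class PairSummary:
    """Period-mean NDVI for the four cells of one pair."""

    site: str
    ndvi_baseline_control: float
    ndvi_baseline_experiment: float
    ndvi_experiment_control: float
    ndvi_experiment_experiment: float

    def __post_init__(self) -> None:
        for v in (
            self.ndvi_baseline_control,
            self.ndvi_baseline_experiment,
            self.ndvi_experiment_control,
            self.ndvi_experiment_experiment,
        ):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"period-mean NDVI {v} outside [-1, 1]")


def select_pairs(
    polygons: Sequence[InterventionPolygon],
    min_gap_years: int = 3,
    min_area_ha: float = 13.0,
    start_year: int = 2010,
) -> list[ControlPair]:
    """All control/experiment pairs satisfying the three criteria.

    Every valid (experiment, control) combination is emitted -- the unit of
    downstream analysis is the pair -- in a deterministic order (site, then
    experiment id, then control id). The input ordering is immaterial.
    """
    pairs = []
    polys = sorted(polygons, key=lambda p: (p.site, p.polygon_id))
    for exp in polys:
        if exp.area_ha < min_area_ha:
            continue
        for ctrl in polys:
            if ctrl.polygon_id == exp.polygon_id and ctrl.site == exp.site:
                continue
            if (
                ctrl.site == exp.site
                and ctrl.zone == exp.zone
                and ctrl.area_ha >= min_area_ha
                and ctrl.intervention_year - exp.intervention_year >= min_gap_years
            ):
                pairs.append(
                    ControlPair(
                        site=exp.site,
                        experiment=exp,
                        control=ctrl,
                        baseline_years=(start_year, exp.intervention_year),
                        experiment_years=(
                            exp.intervention_year + 1,
                            ctrl.intervention_year,
                        ),
                    )
                )
    return pairs


def pair_period_means(pair: ControlPair, monthly: pd.DataFrame) -> PairSummary:
    """Mean monthly NDVI in each period for each member (all months, not
    just the peak window: the comparison tracks whole-season greenness)."""

    def period_mean(polygon_id: int, years: tuple[int, int]) -> float:
        lo, hi = years
        sel = monthly[
            (monthly["site"] == pair.site)
            & (monthly["polygon_id"] == polygon_id)
            & (monthly["year"] >= lo)
            & (monthly["year"] <= hi)
            & monthly["ndvi"].notna()
        ]
        if sel.empty:
            raise ValueError(
                f"no monthly NDVI for polygon {polygon_id} in {lo}-{hi}"
            )
        return float(sel["ndvi"].mean())

    return PairSummary(
        site=pair.site,
        ndvi_baseline_control=period_mean(pair.control.polygon_id, pair.baseline_years),
        ndvi_baseline_experiment=period_mean(pair.experiment.polygon_id, pair.baseline_years),
        ndvi_experiment_control=period_mean(pair.control.polygon_id, pair.experiment_years),
        ndvi_experiment_experiment=period_mean(pair.experiment.polygon_id, pair.experiment_years),
    )


@dataclass(frozen=True)
class PairSignificance:
    baseline_mean_diff: float  # experiment - control during baseline
    baseline_t: float
    baseline_p: float
    experiment_mean_diff: float  # experiment - control during experiment
    experiment_t: float
    experiment_p: float
    adjusted_diff: float  # experiment-period diff net of baseline diff


def pair_significance(summaries: Sequence[PairSummary]) -> PairSignificance:
    """Paired two-tailed t-tests of experiment vs control member means,
    separately for the baseline and experiment periods."""
    if len(summaries) < 2:
        raise ValueError("need >= 2 pairs for a paired test")
    cb = np.array([s.ndvi_baseline_control for s in summaries])
    eb = np.array([s.ndvi_baseline_experiment for s in summaries])
    ce = np.array([s.ndvi_experiment_control for s in summaries])
    ee = np.array([s.ndvi_experiment_experiment for s in summaries])
    if np.ptp(eb - cb) == 0 and (eb - cb)[0] == 0:
        bt, bp = 0.0, 1.0
    else:
        res = stats.ttest_rel(eb, cb)
        bt, bp = float(res.statistic), float(res.pvalue)
    if np.ptp(ee - ce) == 0 and (ee - ce)[0] == 0:
        et, ep = 0.0, 1.0
    else:
        res = stats.ttest_rel(ee, ce)
        et, ep = float(res.statistic), float(res.pvalue)
    bdiff = float((eb - cb).mean())
    ediff = float((ee - ce).mean())
    return PairSignificance(
        baseline_mean_diff=bdiff,
        baseline_t=bt,
        baseline_p=bp,
        experiment_mean_diff=ediff,
        experiment_t=et,
        experiment_p=ep,
        adjusted_diff=ediff - bdiff,
    )


def summaries_to_frame(summaries: Sequence[PairSummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "site": s.site,
                "ndvi_baseline_control": s.ndvi_baseline_control,
                "ndvi_baseline_experiment": s.ndvi_baseline_experiment,
                "ndvi_experiment_control": s.ndvi_experiment_control,
                "ndvi_experiment_experiment": s.ndvi_experiment_experiment,
            }
            for s in summaries
        ]
    )
    mean_row = df.drop(columns="site").mean().to_dict()
    mean_row["site"] = "Mean"
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)[df.columns]
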