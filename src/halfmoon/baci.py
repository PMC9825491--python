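"""Before-After-Control-Impact contrast and pairs bootstrap.

The BACI contrast is (control after - control before) - (experiment after -
experiment before), pooled over pairs: negative when the experiment member
gained more greenness than its control. The relative contrast normalizes by
the experiment members' mean baseline NDVI, giving a unitless effect size.
With only a handful of pairs, uncertainty is assessed by resampling pairs
with replacement (the pair is the exchangeable unit) and reporting the
percentile interval of the resampled contrasts.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .pairing import PairSummary


@dataclass
class BACIResult:
    contrast: float
    relative_contrast: float
    bootstrap_estimates: list[float]
    n_iterations: int
    interval: tuple[float, float]
    seed: int | None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "contrast": self.contrast,
            "relative_contrast": self.relative_contrast,
            "relative_contrast_pct_magnitude": abs(self.relative_contrast) * 100.0,
            "n_iterations": self.n_iterations,
            "interval": list(self.interval),
            "seed": self.seed,
            "bootstrap_estimates": self.bootstrap_estimates,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def baci_contrast(summaries: Sequence[PairSummary]) -> float:
    """Pooled BACI contrast over pairs (mean of per-pair contrasts)."""
    if not summaries:
        raise ValueError("need >= 1 pair")
    per_pair = [
        (s.ndvi_experiment_control - s.ndvi_baseline_control)
        - (s.ndvi_experiment_experiment - s.ndvi_baseline_experiment)
        for s in summaries
    ]
    return float(np.mean(per_pair))


def relative_contrast(contrast: float, baseline_experiment_mean: float) -> float:
    """Contrast / mean baseline NDVI of the experiment members (signed)."""
    if baseline_experiment_mean == 0:
        raise ZeroDivisionError("zero baseline NDVI")
    return float(contrast / baseline_experiment_mean)


def baseline_experiment_mean(summaries: Sequence[PairSummary]) -> float:
    return float(np.mean([s.ndvi_baseline_experiment for s in summaries]))


def bootstrap_baci(
    summaries: Sequence[PairSummary],
    n_iterations: int = 50,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BACIResult:
    """Pairs bootstrap of the BACI contrast.

    The point estimate is the contrast on the full pair set; each iteration
    resamples the pairs with replacement and recomputes the contrast. The
    interval is the 2.5/97.5 percentile of the resampled contrasts.
    Deterministic under a fixed ``seed`` (ignored when ``rng`` is given).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 pairs to bootstrap")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    summaries = list(summaries)
    point = baci_contrast(summaries)
    estimates = []
    for _ in range(n_iterations):
        idx = rng.integers(0, len(summaries), size=len(summaries))
        estimates.append(baci_contrast([summaries[i] for i in idx]))
    low, high = np.percentile(estimates, [2.5, 97.5])
    return BACIResult(
        contrast=point,
        relative_contrast=relative_contrast(point, baseline_experiment_mean(summaries)),
        bootstrap_estimates=[float(e) for e in estimates],
        n_iterations=n_iterations,
        interval=(float(low), float(high)),
        seed=seed,
    )
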