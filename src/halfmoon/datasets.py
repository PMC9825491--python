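"""Bundled CSV fixtures: the published site summary and control-pair tables.

``table1.csv`` holds the 18-site before/after summary (mean annual peak
NDVI Aug-Oct and mean Jun-Aug rainfall totals) with the percent-difference
columns as printed in the source; ``table2.csv`` the seven control/
experiment pairs with their period-mean NDVI values. These are inputs for
desk-reproduction of the published analysis, not outputs of this package.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .pairing import PairSummary


def _read(name: str) -> pd.DataFrame:
    with resources.files("halfmoon.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_site_summary() -> pd.DataFrame:
    """The 18-site pre/post summary table (Table 1 analogue)."""
    return _read("table1.csv")


def load_control_pairs() -> pd.DataFrame:
    """The seven control/experiment pairs table (Table 2 analogue)."""
    return _read("table2.csv")


def control_pair_summaries() -> list[PairSummary]:
    """The seven pairs as :class:`PairSummary` objects."""
    df = load_control_pairs()
    return [
        PairSummary(
            site=row["site"],
            ndvi_baseline_control=row["ndvi_baseline_control"],
            ndvi_baseline_experiment=row["ndvi_baseline_experiment"],
            ndvi_experiment_control=row["ndvi_experiment_control"],
            ndvi_experiment_experiment=row["ndvi_experiment_experiment"],
        )
        for _, row in df.iterrows()
    ]
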