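"""ELISpot spot-count normalization and positivity calling.

An IFN-γ ELISpot well reports a spot count for a known number of plated
cells. Counts are normalized to spots per 10^6 cells so wells with
different plating densities are comparable, summarized per condition as a
mean rate with SEM over replicate wells, and a condition is called positive
by a dual rule: the mean rate must exceed ``rate_min`` (default 20 spots
per 10^6 cells, strict inequality) AND be at least ``fold_min`` (default
3-fold) above the non-stimulated control from the same donor.

A non-stimulated control with mean rate zero is handled with a floor of
``epsilon`` (default 1 spot per 10^6 cells) so the fold ratio is defined;
with a zero control, the fold criterion then reduces to
mean_rate >= fold_min * epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

WELL_COLUMNS = ["condition", "donor", "replicate", "spots", "cells_plated"]


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    donor: str
    n_replicates: int
    mean_rate: float  # spots per 10^6 cells
    sem: float


@dataclass(frozen=True)
class PositivityCall:
    condition: str
    donor: str
    mean_rate: float
    sem: float
    fold_over_nc: float
    positive: bool


def normalize_rates(wells: pd.DataFrame) -> pd.DataFrame:
    """Per (donor, condition) mean spot rate and SEM, in spots per 10^6 cells.

    rate_i = spots_i * 10^6 / cells_plated_i; SEM is sample SD (ddof=1) over
    sqrt(n), defined as 0 for a single replicate.
    """
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    if len(wells) == 0:
        raise ValueError("empty well table")
    if (wells["spots"] < 0).any():
        raise ValueError("negative spot count")
    if (wells["cells_plated"] <= 0).any():
        raise ValueError("non-positive cells_plated")
    df = wells.copy()
    df["rate"] = df["spots"] * 1e6 / df["cells_plated"]

    def _summ(g: pd.Series) -> pd.Series:
        n = len(g)
        sem = 0.0 if n == 1 else float(np.std(g, ddof=1) / math.sqrt(n))
        return pd.Series({"n_replicates": n, "mean_rate": float(np.mean(g)), "sem": sem})

    out = df.groupby(["donor", "condition"])["rate"].apply(_summ).unstack()
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out.reset_index()


def get_summary(rates: pd.DataFrame, donor: str, condition: str) -> ConditionSummary:
    row = rates[(rates["donor"] == donor) & (rates["condition"] == condition)]
    if len(row) == 0:
        raise ValueError(f"condition {condition!r} absent for donor {donor!r}")
    r = row.iloc[0]
    return ConditionSummary(
        condition=condition, donor=donor, n_replicates=int(r["n_replicates"]),
        mean_rate=float(r["mean_rate"]), sem=float(r["sem"]),
    )


def call_positive(
    test: ConditionSummary,
    nc: ConditionSummary,
    rate_min: float = 20.0,
    fold_min: float = 3.0,
    epsilon: float = 1.0,
) -> PositivityCall:
    """Dual positivity rule: rate strictly above ``rate_min`` AND at least
    ``fold_min``-fold over the same-donor non-stimulated control."""
    if test.donor != nc.donor:
        raise ValueError("test and control summaries are from different donors")
    denom = max(nc.mean_rate, epsilon)
    fold = test.mean_rate / denom
    positive = (test.mean_rate > rate_min) and (fold >= fold_min)
    return PositivityCall(
        condition=test.condition, donor=test.donor, mean_rate=test.mean_rate,
        sem=test.sem, fold_over_nc=fold, positive=positive,
    )


def call_all(
    wells: pd.DataFrame,
    nc_label: str = "NC",
    rate_min: float = 20.0,
    fold_min: float = 3.0,
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Positivity calls for every non-control condition, per donor."""
    rates = normalize_rates(wells)
    calls = []
    for donor in sorted(rates["donor"].unique()):
        nc = get_summary(rates, donor, nc_label)
        sub = rates[rates["donor"] == donor]
        for condition in sorted(sub["condition"].unique()):
            if condition == nc_label:
                continue
            c = call_positive(
                get_summary(rates, donor, condition), nc,
                rate_min=rate_min, fold_min=fold_min, epsilon=epsilon,
            )
            calls.append(vars(c))
    return pd.DataFrame(calls)
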