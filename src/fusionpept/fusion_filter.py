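"""Multi-caller consensus filtering of gene-fusion call tables.

Fusion callers applied to tumor/normal RNA-seq emit candidate fusions with
junction-crossing (split) and fragment-spanning read support. Spanning-only
support is a known source of false positives, and fusions also present in
adjacent normal tissue are unlikely to be tumor-specific. The shipped
pipeline therefore applies four stages, in order:

1. subtract fusions seen in any adjacent-normal sample (cohort-wide),
2. keep only fusions reported by every caller for that tumor sample,
3. require split-read support,
4. intersect with an actionable-gene list (either partner).

Fusion identity for matching is the ordered (gene5, gene3) symbol pair,
compared case-insensitively; breakpoint coordinates are ignored because
callers disagree on them.
"""

from __future__ import annotations

import logging

import numpy as np
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

CALL_COLUMNS = [
    "sample_id", "tissue", "caller", "gene5", "gene3", "split_reads", "spanning_reads",
]


@dataclass
class FilterReport:
    """Per-stage survival counts for the four-stage consensus filter."""

    input_counts_per_caller: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)  # stage name -> n rows
    positive_hits: list = field(default_factory=list)  # (gene5, gene3, sample_id)

    def to_dict(self) -> dict:
        return {
            "input_counts_per_caller": self.input_counts_per_caller,
            "stage_counts": self.stage_counts,
            "positive_hits": [list(h) for h in self.positive_hits],
        }


def _norm_gene(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.upper()


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"fusion call table missing columns: {missing}")
    calls = calls.copy()
    calls["gene5"] = _norm_gene(calls["gene5"])
    calls["gene3"] = _norm_gene(calls["gene3"])
    if (calls["gene5"] == "").any() or (calls["gene3"] == "").any():
        raise ValueError("empty gene symbol in fusion call table")
    bad = ~calls["tissue"].isin(["tumor", "normal"])
    if bad.any():
        raise ValueError(f"unknown tissue labels: {sorted(calls.loc[bad, 'tissue'].unique())}")
    support = calls["split_reads"].astype(int) + calls["spanning_reads"].astype(int)
    if (support < 1).any():
        raise ValueError("call with no read support (split + spanning == 0)")
    return calls


def subtract_normal_background(calls: pd.DataFrame) -> pd.DataFrame:
    """Drop every tumor call whose (gene5, gene3) pair occurs in any normal.

    Normal-tissue rows themselves are removed from the output. Matching is
    cohort-wide: a fusion seen in any normal sample, by any caller, removes
    it from all tumors.
    """
    calls = validate_calls(calls)
    normals = calls[calls["tissue"] == "normal"]
    background = set(zip(normals["gene5"], normals["gene3"]))
    tumor = calls[calls["tissue"] == "tumor"]
    keep = np.fromiter(
        (pair not in background for pair in zip(tumor["gene5"], tumor["gene3"])),
        dtype=bool, count=len(tumor),
    )
    return tumor[keep].reset_index(drop=True)


def require_all_callers(calls: pd.DataFrame, caller_set: set[str]) -> pd.DataFrame:
    """Keep a (sample, gene5, gene3) hit only if every caller reports it.

    Rows from callers outside ``caller_set`` are ignored with a warning.
    One representative row per caller is kept for surviving hits.
    """
    if not caller_set:
        raise ValueError("caller_set must be non-empty")
    calls = validate_calls(calls)
    unknown = set(calls["caller"]) - set(caller_set)
    if unknown:
        log.warning("ignoring calls from callers outside caller_set: %s", sorted(unknown))
        calls = calls[calls["caller"].isin(caller_set)]
    key = ["sample_id", "gene5", "gene3"]
    n_callers = calls.groupby(key)["caller"].nunique()
    full = n_callers[n_callers == len(caller_set)].index
    idx = pd.MultiIndex.from_frame(calls[key])
    out = calls[idx.isin(full)]
    # one representative row per (hit, caller)
    out = out.drop_duplicates(subset=key + ["caller"])
    return out.reset_index(drop=True)


def require_split_reads(calls: pd.DataFrame, min_split: int = 1) -> pd.DataFrame:
    """Keep rows with split_reads >= min_split; spanning reads never qualify."""
    if min_split < 1:
        raise ValueError("min_split must be >= 1")
    calls = validate_calls(calls)
    return calls[calls["split_reads"].astype(int) >= min_split].reset_index(drop=True)


def filter_actionable(calls: pd.DataFrame, actionable_genes: set[str]) -> pd.DataFrame:
    """Keep rows where either fusion partner is in the actionable-gene list."""
    if not actionable_genes:
        raise ValueError("actionable_genes must be non-empty")
    calls = validate_calls(calls)
    genes = {g.strip().upper() for g in actionable_genes}
    keep = calls["gene5"].isin(genes) | calls["gene3"].isin(genes)
    return calls[keep].reset_index(drop=True)


def run_filter_pipeline(
    calls: pd.DataFrame,
    caller_set: set[str],
    actionable_genes: set[str],
    min_split: int = 1,
) -> tuple[pd.DataFrame, FilterReport]:
    """Four-stage consensus filter; returns surviving calls and a report."""
    calls = validate_calls(calls)
    report = FilterReport(
        input_counts_per_caller=calls["caller"].value_counts().to_dict()
    )
    stages = [
        ("background_subtracted", lambda c: subtract_normal_background(c)),
        ("all_callers", lambda c: require_all_callers(c, caller_set)),
        ("split_reads", lambda c: require_split_reads(c, min_split)),
        ("actionable", lambda c: filter_actionable(c, actionable_genes)),
    ]
    out = calls
    report.stage_counts["input"] = len(out)
    for name, fn in stages:
        out = fn(out)
        report.stage_counts[name] = len(out)
    report.positive_hits = sorted(
        set(zip(out["gene5"], out["gene3"], out["sample_id"]))
    )
    return out, report


def read_calls_tsv(path, column_map: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    return validate_calls(df)


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}
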