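"""Off-target (cross-reactivity) hit binning and least-hits ranking.

A cross-reactivity screen returns, for each candidate 9-mer, self-derived
peptides with biochemically similar profiles and a p-value per hit. This
module consumes such a hit table, assigns each hit to one of three p-value
bins — strict (0, 0.005], mid (0.005, 0.01], lenient (0.01, 0.05] by
default — discards (but counts) hits above the lenient cutoff, and ranks
query peptides ascending by their weighted off-target burden, so the
peptide with the fewest credible off-targets ranks first.

Tissue-expression labels on hits are carried through unchanged; they are
annotations from the upstream screen, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

BIN_NAMES = ("strict", "mid", "lenient")


@dataclass(frozen=True)
class OffTargetHit:
    query_peptide: str
    hit_peptide: str
    p_value: float
    tissue_labels: tuple = ()

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def bin_hits(
    hits: Iterable[OffTargetHit],
    strict: float = 0.005,
    mid: float = 0.01,
    lenient: float = 0.05,
) -> pd.DataFrame:
    """Per-query hit counts in (0, strict], (strict, mid], (mid, lenient].

    Bin edges are inclusive on the upper side, so a hit at exactly the
    strict cutoff falls in the strict bin. Hits with p above ``lenient``
    are excluded from the bins but counted in a ``discarded`` column, so
    strict + mid + lenient + discarded equals the input row count per query.
    """
    if not strict < mid < lenient:
        raise ValueError("bin edges must satisfy strict < mid < lenient")
    rows = []
    for h in hits:
        if h.p_value <= strict:
            b = "strict"
        elif h.p_value <= mid:
            b = "mid"
        elif h.p_value <= lenient:
            b = "lenient"
        else:
            b = "discarded"
        rows.append({"query_peptide": h.query_peptide, "bin": b})
    if not rows:
        return pd.DataFrame(columns=["query_peptide", *BIN_NAMES, "discarded"])
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["query_peptide", "bin"]).size().unstack(fill_value=0)
    )
    for col in (*BIN_NAMES, "discarded"):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[[*BIN_NAMES, "discarded"]].reset_index()
    counts.columns.name = None
    return counts


def rank_queries_by_hits(
    binned: pd.DataFrame, weights: Sequence[float] = (1.0, 1.0, 1.0)
) -> list[str]:
    """Queries ascending by weighted bin total; fewest off-targets first.

    Ties break by strict-bin count, then lexicographically.
    """
    if any(w < 0 for w in weights):
        raise ValueError("bin weights must be >= 0")
    df = binned.copy()
    df["total"] = sum(w * df[b] for w, b in zip(weights, BIN_NAMES))
    df = df.sort_values(["total", "strict", "query_peptide"], kind="mergesort")
    return df["query_peptide"].tolist()


def read_hits_tsv(path) -> list[OffTargetHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for _, row in df.iterrows():
        tissues: tuple = ()
        if "tissue_labels" in df.columns and isinstance(row.get("tissue_labels"), str):
            tissues = tuple(t for t in row["tissue_labels"].split(",") if t)
        hits.append(
            OffTargetHit(
                query_peptide=str(row["query_peptide"]),
                hit_peptide=str(row["hit_peptide"]),
                p_value=float(row["p_value"]),
                tissue_labels=tissues,
            )
        )
    return hits
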