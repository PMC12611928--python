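"""Clonotype expansion statistics and per-cell gene-module scores.

Input is a per-cell table with barcode, donor, condition (stimulated /
nonstimulated), an assigned cell state (active / exhausted / naive /
other), and paired CDR3α/CDR3β amino-acid sequences. A clonotype is keyed
by the CDR3α+CDR3β pair; a clonotype is "expanded" when carried by more
than one cell. Clonotypes responding to peptide stimulation (rather than
to cytokine media) are ranked by the proportion of each clonotype's cells
that come from stimulated samples.

Gene-module scores follow the binned-control scheme: the score of a cell
is the mean expression of the module genes minus the mean expression of
control genes sampled, per module gene, from the same gene-wise mean
expression bin, which cancels depth/abundance effects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CELL_COLUMNS = ["barcode", "donor", "condition", "cell_state", "cdr3a", "cdr3b"]
CONDITIONS = ("stimulated", "nonstimulated")


def add_clonotype_ids(cells: pd.DataFrame, sep: str = "_") -> pd.DataFrame:
    """Attach clonotype_id = CDR3α + sep + CDR3β; empty for cells lacking a chain.

    Cells without both chains are excluded from clonotype statistics but
    retained for composition breakdowns.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    df = cells.copy()
    a = df["cdr3a"].fillna("").astype(str).str.strip()
    b = df["cdr3b"].fillna("").astype(str).str.strip()
    has_both = (a != "") & (b != "")
    df["clonotype_id"] = np.where(has_both, a + sep + b, "")
    return df


def _tcr_cells(cells: pd.DataFrame) -> pd.DataFrame:
    if "clonotype_id" not in cells.columns:
        cells = add_clonotype_ids(cells)
    return cells[cells["clonotype_id"] != ""]


def expanded_clonotype_count(cells: pd.DataFrame, group_by: str = "cell_state") -> pd.Series:
    """Per group, the number of distinct clonotypes seen in >= 2 cells."""
    df = _tcr_cells(cells)
    counts = df.groupby([group_by, "clonotype_id"]).size()
    expanded = counts[counts >= 2]
    out = expanded.groupby(level=0).size()
    return out.reindex(sorted(df[group_by].unique()), fill_value=0)


def summarize_clonotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-clonotype cell counts, stimulated proportion, and breakdowns."""
    df = _tcr_cells(cells)
    rows = []
    for ct, g in df.groupby("clonotype_id"):
        n = len(g)
        n_stim = int((g["condition"] == "stimulated").sum())
        rows.append(
            {
                "clonotype_id": ct,
                "n_cells": n,
                "n_stimulated": n_stim,
                "stim_proportion": n_stim / n,
                "donor_counts": g["donor"].value_counts().to_dict(),
                "state_counts": g["cell_state"].value_counts().to_dict(),
            }
        )
    return pd.DataFrame(rows)


def rank_top_clonotypes(
    cells: pd.DataFrame, top_n: int = 15, normalized: bool = False
) -> pd.DataFrame:
    """Top clonotypes by stimulated proportion.

    Default ranks by the proportion of the clonotype's cells that are
    stimulated; ``normalized`` instead uses condition-size-normalized rates
    (per-condition frequency of the clonotype), which corrects for unequal
    numbers of stimulated and non-stimulated cells. Ties break by n_cells
    descending, then clonotype_id, making the ranking stable under input
    row order.
    """
    df = _tcr_cells(cells)
    present = set(df["condition"].unique())
    if not set(CONDITIONS) <= present:
        raise ValueError(f"both conditions required, found {sorted(present)}")
    summ = summarize_clonotypes(df)
    if normalized:
        n_by_cond = df["condition"].value_counts()
        stim_rate = summ["n_stimulated"] / n_by_cond["stimulated"]
        non_rate = (summ["n_cells"] - summ["n_stimulated"]) / n_by_cond["nonstimulated"]
        with np.errstate(invalid="ignore"):
            summ["rank_key"] = stim_rate / (stim_rate + non_rate)
    else:
        summ["rank_key"] = summ["stim_proportion"]
    summ = summ.sort_values(
        ["rank_key", "n_cells", "clonotype_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if len(summ) < top_n:
        log.warning("only %d clonotypes available (top_n=%d)", len(summ), top_n)
    out = summ.head(top_n).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def composition_breakdown(cells: pd.DataFrame, by: str, within: str | None = None) -> pd.DataFrame:
    """Proportion of cells per category of ``by`` (optionally within groups).

    Proportions sum to 1 within each margin.
    """
    if by not in cells.columns:
        raise ValueError(f"unknown column {by!r}")
    if within is None:
        prop = cells[by].value_counts(normalize=True).sort_index()
        return prop.rename_axis(by).reset_index(name="proportion")
    prop = (
        cells.groupby(within)[by].value_counts(normalize=True)
        .rename("proportion").reset_index()
    )
    return prop


def score_gene_module(
    expr: pd.DataFrame,
    genes: list[str],
    n_bins: int = 25,
    n_control_per_gene: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    ``expr`` is cells x genes (non-negative). Genes are binned into
    ``n_bins`` equal-size bins of gene-wise mean expression; for each module
    gene, ``n_control_per_gene`` control genes are sampled (with
    replacement, seeded) from its bin, excluding module genes. The score is
    mean(module genes) - mean(control pool) per cell. Module genes absent
    from the matrix are dropped with a warning; no gene present is an error.
    """
    present = [g for g in genes if g in expr.columns]
    absent = [g for g in genes if g not in expr.columns]
    if absent:
        log.warning("module genes absent from matrix: %s", absent)
    if not present:
        raise ValueError("no module gene present in the expression matrix")
    gene_means = expr.mean(axis=0)
    order = gene_means.sort_values(kind="mergesort")
    n_genes = len(order)
    bin_size = max(1, int(np.ceil(n_genes / n_bins)))
    bin_of = pd.Series(np.arange(n_genes) // bin_size, index=order.index)
    rng = np.random.default_rng(seed)
    module_set = set(present)
    control: list[str] = []
    for g in present:
        pool = bin_of.index[(bin_of == bin_of[g]) & (~bin_of.index.isin(module_set))]
        if len(pool) == 0:
            log.warning("no control candidates in bin of gene %s", g)
            continue
        control.extend(rng.choice(pool, size=n_control_per_gene, replace=True))
    control_unique = sorted(set(control))
    module_mean = expr[present].mean(axis=1)
    if control_unique:
        control_mean = expr[control_unique].mean(axis=1)
    else:
        control_mean = pd.Series(0.0, index=expr.index)
    return (module_mean - control_mean).rename("module_score")


# Default module gene sets (activation / exhaustion / naive programs).
ACTIVATION_GENES = ["IFNG", "TNF", "GZMB", "CCL3"]
EXHAUSTION_GENES = [
    "LILRB1", "PDCD1", "LAYN", "HAVCR2", "LAG3", "CD244", "CTLA4", "TIGIT",
    "TOX", "VSIR", "BTLA", "ENTPD1", "CD160", "LAIR1", "GZMK",
]
NAIVE_GENES = [
    "IL7R", "CCR7", "SELL", "FOXO1", "KLF2", "KLF3", "LEF1", "TCF7", "ACTN1", "FOXP1",
]
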