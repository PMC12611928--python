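"""Junction peptide tiling and MHC class I binder consensus selection.

Given the protein of a fusion ORF and the junction position in protein
coordinates, this module tiles every k-mer window that crosses the junction
(the candidate neoantigens: for an interior junction and k = 9 that is
exactly 8 windows), derives wild-type control k-mers drawn entirely from one
parent and offset a fixed gap from the junction, parses predictor output
tables in two dialects (IC50 in nM, and %Rank), and applies the dual-
predictor consensus rule: a (peptide, allele) pair is a strong binder by
IC50 iff IC50 <= 500 nM, by rank iff %Rank <= 10, and a consensus binder iff
both. Alleles are then ranked by the number of distinct strong junction
peptides they bind.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class JunctionPeptide:
    """A k-mer window on the fusion protein.

    ``protein_start`` is 1-based. ``n_from_5prime`` counts residues encoded
    by the 5' parent: between 1 and k-1 for junction-spanning windows, and
    exactly 0 or k for wild-type controls.
    """

    sequence: str
    protein_start: int
    n_from_5prime: int
    is_wildtype_control: bool = False
    control_parent: Optional[str] = None


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: str
    metric: str  # "ic50_nM" | "pct_rank"
    value: float
    source: str = ""


@dataclass(frozen=True)
class BinderCall:
    peptide: str
    allele: str
    strong_by: frozenset
    consensus: bool


def tile_junction_peptides(
    protein: str, junction_index: int, k: int = 9
) -> list[JunctionPeptide]:
    """All k-mer windows containing at least one residue from each parent.

    The junction lies between residues ``junction_index`` and
    ``junction_index + 1`` (1-based). For a junction with full flanks this
    yields exactly k-1 windows; near a terminus fewer windows exist and a
    warning is logged.
    """
    n = len(protein)
    if not 1 <= junction_index <= n - 1:
        raise ValueError(f"junction_index {junction_index} outside [1, {n - 1}]")
    if n < k:
        raise ValueError(f"protein shorter than k={k}")
    lo = max(1, junction_index - k + 2)
    hi = min(junction_index, n - k + 1)
    windows = []
    for s in range(lo, hi + 1):
        windows.append(
            JunctionPeptide(
                sequence=protein[s - 1 : s - 1 + k],
                protein_start=s,
                n_from_5prime=junction_index - s + 1,
            )
        )
    if len(windows) < k - 1:
        log.warning(
            "junction too close to a terminus: %d of %d possible windows",
            len(windows), k - 1,
        )
    return windows


def wildtype_controls(
    protein: str,
    junction_index: int,
    gap: int = 2,
    k: int = 9,
    parents: tuple[str, str] = ("5prime", "3prime"),
) -> tuple[JunctionPeptide, JunctionPeptide]:
    """Two single-parent control k-mers, ``gap`` residues from the junction.

    The 5'-parent control ends ``gap`` residues before the junction; the
    3'-parent control begins ``gap`` residues after it. Neither crosses the
    junction.
    """
    n = len(protein)
    if junction_index < k + gap:
        raise ValueError("insufficient 5' flank for wild-type control")
    if n - junction_index < k + gap:
        raise ValueError("insufficient 3' flank for wild-type control")
    s5 = junction_index - gap - k + 1
    s3 = junction_index + gap + 1
    wt5 = JunctionPeptide(
        sequence=protein[s5 - 1 : s5 - 1 + k], protein_start=s5,
        n_from_5prime=k, is_wildtype_control=True, control_parent=parents[0],
    )
    wt3 = JunctionPeptide(
        sequence=protein[s3 - 1 : s3 - 1 + k], protein_start=s3,
        n_from_5prime=0, is_wildtype_control=True, control_parent=parents[1],
    )
    return wt5, wt3


_HLA_RE = re.compile(
    r"^(?:HLA-?)?([ABC])\*?(\d{1,3})[:\-](\d{1,3})(?:[:\-]\d+)*$", re.IGNORECASE
)


def normalize_hla(name: str) -> str:
    """Canonicalize 2-field class I HLA names: "HLA-<locus>*<gg>:<pp>".

    Accepts the common dialects ("HLA-C07:02", "hla-a*2:1", "C0702");
    fields beyond the second are dropped. Unparseable names raise.
    """
    s = name.strip()
    m = _HLA_RE.match(s)
    if m is None:
        # no separator dialect, e.g. C0702 / HLA-C0702: split a 4-digit run
        m2 = re.match(r"^(?:HLA-?)?([ABC])\*?(\d{4})$", s, re.IGNORECASE)
        if m2 is None:
            raise ValueError(f"unrecognized HLA name: {name!r}")
        locus, digits = m2.group(1).upper(), m2.group(2)
        group, prot = digits[:2], digits[2:]
    else:
        locus = m.group(1).upper()
        group, prot = m.group(2), m.group(3)
    return f"HLA-{locus}*{int(group):02d}:{int(prot):02d}"


_DEFAULT_ALIASES = {
    "peptide": ["peptide", "Peptide", "peptide_seq", "sequence"],
    "allele": ["allele", "Allele", "hla", "HLA", "mhc"],
    "value": ["value", "ic50", "IC50", "ic50_nM", "rank", "%rank", "pct_rank", "Rank"],
}


def _read_predictor_table(path, metric: str, source: str, column_map=None):
    df = pd.read_csv(path, sep="\t")
    cols = {}
    for want, aliases in _DEFAULT_ALIASES.items():
        if column_map and want in column_map:
            aliases = [column_map[want]]
        hit = next((a for a in aliases if a in df.columns), None)
        if hit is None:
            raise ValueError(f"column for {want!r} not found in {path}")
        cols[want] = hit
    preds: list[BindingPrediction] = []
    for i in range(len(df)):
        lineno = i + 2  # header is line 1
        raw = df.iloc[i][cols["value"]]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            log.warning("%s line %d: non-numeric value %r, row rejected", path, lineno, raw)
            continue
        if value <= 0 or (metric == "pct_rank" and value > 100):
            log.warning("%s line %d: value %s out of range, row rejected", path, lineno, value)
            continue
        preds.append(
            BindingPrediction(
                peptide=str(df.iloc[i][cols["peptide"]]).strip().upper(),
                allele=normalize_hla(str(df.iloc[i][cols["allele"]])),
                metric=metric,
                value=value,
                source=source,
            )
        )
    return preds


def read_ic50_table(path, source: str = "ic50", column_map=None) -> list[BindingPrediction]:
    """Parse an IC50-dialect predictor table (TSV; values in nM)."""
    return _read_predictor_table(path, "ic50_nM", source, column_map)


def read_rank_table(path, source: str = "rank", column_map=None) -> list[BindingPrediction]:
    """Parse a %Rank-dialect predictor table (TSV; values in (0, 100])."""
    return _read_predictor_table(path, "pct_rank", source, column_map)


def write_predictions_tsv(preds: Iterable[BindingPrediction], path) -> None:
    pd.DataFrame(
        [{"peptide": p.peptide, "allele": p.allele, "value": p.value} for p in preds]
    ).to_csv(path, sep="\t", index=False)


def select_strong_binders(
    preds: Iterable[BindingPrediction],
    ic50_max: float = 500.0,
    rank_max: float = 10.0,
) -> list[BinderCall]:
    """Dual-predictor consensus: strong iff IC50 <= ic50_max or %Rank <= rank_max.

    Multiple predictions for one (peptide, allele, metric) are reduced to the
    best (minimum) value. Consensus requires strength under both metrics.
    """
    if ic50_max <= 0 or rank_max <= 0:
        raise ValueError("thresholds must be > 0")
    best: dict[tuple[str, str, str], float] = {}
    for p in preds:
        key = (p.peptide, p.allele, p.metric)
        best[key] = min(best.get(key, float("inf")), p.value)
    pairs = sorted({(pep, al) for pep, al, _ in best})
    calls = []
    for pep, al in pairs:
        strong = set()
        if best.get((pep, al, "ic50_nM"), float("inf")) <= ic50_max:
            strong.add("ic50")
        if best.get((pep, al, "pct_rank"), float("inf")) <= rank_max:
            strong.add("rank")
        calls.append(
            BinderCall(
                peptide=pep, allele=al, strong_by=frozenset(strong),
                consensus=strong >= {"ic50", "rank"},
            )
        )
    return calls


def rank_alleles(
    calls: Iterable[BinderCall],
    junction_only: bool = True,
    wildtype_peptides: set[str] | None = None,
    require_consensus: bool = False,
) -> list[tuple[str, int]]:
    """Rank alleles by number of distinct strong peptides bound.

    With ``junction_only``, peptides listed in ``wildtype_peptides`` do not
    count, so an allele strong only for wild-type controls ranks with 0.
    ``require_consensus`` restricts counting to consensus calls; otherwise
    any strength (either metric) counts.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no binder calls to rank")
    wt = {p.upper() for p in (wildtype_peptides or set())}
    per_allele: dict[str, set[str]] = {}
    for c in calls:
        per_allele.setdefault(c.allele, set())
        qualifies = c.consensus if require_consensus else bool(c.strong_by)
        if not qualifies:
            continue
        if junction_only and c.peptide in wt:
            continue
        per_allele[c.allele].add(c.peptide)
    return sorted(
        ((a, len(peps)) for a, peps in per_allele.items()),
        key=lambda t: (-t[1], t[0]),
    )


def peptides_to_tsv(peps: Iterable[JunctionPeptide], path) -> None:
    pd.DataFrame(
        [
            {
                "sequence": p.sequence,
                "protein_start": p.protein_start,
                "n_from_5prime": p.n_from_5prime,
                "is_wildtype_control": p.is_wildtype_control,
                "control_parent": p.control_parent or "",
            }
            for p in peps
        ]
    ).to_csv(path, sep="\t", index=False)


def peptides_to_fasta(peps: Iterable[JunctionPeptide], path) -> None:
    with open(path, "w") as fh:
        for p in peps:
            tag = "wt" if p.is_wildtype_control else "junction"
            fh.write(
                f">{p.sequence} start={p.protein_start} n5={p.n_from_5prime} {tag}\n"
                f"{p.sequence}\n"
            )
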