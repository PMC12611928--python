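"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator is a pure function of (seed, parameters): the same inputs
regenerate byte-identical data. Each generator draws from its own RNG
stream, derived from the master seed and a stable per-generator label, so
adding or reordering generators never perturbs another's output. Every
generator returns (data, truth) where truth is a JSON-serializable record
sufficient to score the downstream stage without re-deriving intent.

Default scales emulate the structure of the study the pipeline targets:
a two-gene fusion with one major junction-spanning ORF, predictor score
tables with planted consensus binders, Poisson ELISpot counts with planted
stimulation effects, a two-donor ~4,000-cell repertoire with 15 planted
expanded clonotypes concentrated in stimulated active/exhausted cells, and
30-sequence CDR3 sets with a planted position-specific motif including
conserved glycines.
"""

from __future__ import annotations

import json
import zlib

import numpy as np
import pandas as pd

from .chimera import GeneSegment, FusionTranscript, build_fusion_transcript, revcomp
from .motif import AA20, CDR3Set

CODON = {  # one representative codon per residue; avoids accidental stops/starts
    "A": "GCT", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCA", "Q": "CAA", "R": "AGA", "S": "TCC", "T": "ACA", "V": "GTC",
    "W": "TGG", "Y": "TAC",
}
AA_NO_M = AA20.replace("M", "")  # internal codons avoid ATG to keep one major start


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream per generator: master seed + stable label hash."""
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


def _random_nt(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_aa(rng, n: int, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def gen_fusion_pair(
    seed: int,
    len_utr5: int = 90,
    len_utr3: int = 90,
    orf_aa: int = 150,
    junction_codon: int = 70,
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
    k: int = 9,
) -> tuple[GeneSegment, GeneSegment, dict]:
    """Two parent segments whose fusion carries a planted spanning ORF.

    The major ORF has ``orf_aa`` residues; the breakpoint falls at the
    codon boundary after residue ``junction_codon`` (counting the
    initiator Met), so residues 1..junction_codon are 5'-parent encoded.
    Optional primers are planted in the UTRs, forward in the 5' UTR and
    the reverse complement of the reverse primer in the 3' UTR, giving an
    amplicon of known length spanning the junction. A stop codon is placed
    in-frame just before the planted ATG so no upstream ATG extends the ORF.
    """
    if len_utr5 < 60 or len_utr3 < 60:
        raise ValueError("UTR lengths must be >= 60")
    if not 1 <= junction_codon < orf_aa:
        raise ValueError("junction_codon must lie inside the ORF")
    rng = _rng(seed, "fusion_pair")
    protein = "M" + _random_aa(rng, orf_aa - 1, AA_NO_M)
    codons = [CODON[a] for a in protein]
    utr5 = _random_nt(rng, len_utr5 - 3) + "TAA"  # in-frame stop guards the ATG
    utr3 = _random_nt(rng, len_utr3)
    if fwd_primer:
        utr5 = fwd_primer + utr5[len(fwd_primer):]
    if rev_primer:
        rc = revcomp(rev_primer)
        utr3 = utr3[: -len(rc)] + rc
    seq5 = utr5 + "".join(codons[:junction_codon])
    seq3 = "".join(codons[junction_codon:]) + "TAA" + utr3
    seg5 = GeneSegment("GENE5P", "five_prime", seq5, "exon 1-15")
    seg3 = GeneSegment("GENE3P", "three_prime", seq3, "exon 12-19")
    junction_index = junction_codon  # 1-based protein residues from 5' parent
    lo = max(1, junction_index - k + 2)
    hi = min(junction_index, orf_aa - k + 1)
    windows = [protein[s - 1 : s - 1 + k] for s in range(lo, hi + 1)]
    truth = {
        "seed": seed,
        "breakpoint": len(seq5),
        "orf_protein": protein,
        "orf_nt_start": len(utr5),
        "junction_protein_index": junction_index,
        "junction_peptides": windows,
        "amplicon_length": (
            len(seq5) + len("".join(codons[junction_codon:])) + 3 + len(utr3)
            if (fwd_primer and rev_primer) else None
        ),
    }
    return seg5, seg3, truth


def gen_predictor_tables(
    seed: int,
    peptides: list[str],
    alleles: list[str],
    n_consensus: int = 4,
    ic50_max: float = 500.0,
    rank_max: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """IC50 and %Rank tables with planted consensus binder pairs.

    Planted pairs sit below both thresholds; every other pair is forced
    above at least one threshold (the weak metric chosen at random), so the
    consensus set is exactly the plant.
    """
    pairs = [(p, a) for p in peptides for a in alleles]
    if n_consensus > len(pairs):
        raise ValueError("n_consensus exceeds number of (peptide, allele) pairs")
    rng = _rng(seed, "predictor_tables")
    planted_idx = rng.choice(len(pairs), size=n_consensus, replace=False)
    planted = {pairs[i] for i in planted_idx}
    ic50_rows, rank_rows = [], []
    for pep, al in pairs:
        if (pep, al) in planted:
            ic50 = float(np.exp(rng.uniform(np.log(1.0), np.log(ic50_max))))
            rank = float(rng.uniform(0.01, rank_max))
        else:
            # force the pair above at least one threshold
            weak_metric = str(rng.choice(["ic50", "rank", "both"]))
            if weak_metric in ("ic50", "both"):
                ic50 = float(np.exp(rng.uniform(np.log(ic50_max * 1.01), np.log(50000.0))))
            else:
                ic50 = float(np.exp(rng.uniform(np.log(1.0), np.log(50000.0))))
            if weak_metric in ("rank", "both"):
                rank = float(rng.uniform(rank_max * 1.01, 100.0))
            else:
                rank = float(rng.uniform(0.01, 100.0)) if ic50 > ic50_max \
                    else float(rng.uniform(rank_max * 1.01, 100.0))
        ic50_rows.append({"peptide": pep, "allele": al, "ic50": round(ic50, 3)})
        rank_rows.append({"peptide": pep, "allele": al, "rank": round(rank, 4)})
    truth = {"seed": seed, "consensus_pairs": sorted([list(p) for p in planted])}
    return pd.DataFrame(ic50_rows), pd.DataFrame(rank_rows), truth


def gen_elispot(
    seed: int,
    conditions: dict[str, float] | None = None,
    nc_rate: float = 5.0,
    n_replicates: int = 3,
    cells_per_well: int = 200_000,
    donor: str = "D1",
    rate_min: float = 20.0,
    fold_min: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Poisson ELISpot wells with planted per-condition stimulation effects.

    ``conditions`` maps condition name -> added rate (spots per 10^6 cells)
    over the non-stimulated baseline ``nc_rate``. Counts are
    Poisson(rate * cells / 10^6). Truth records which conditions are
    positive in expectation under the dual rule.
    """
    if conditions is None:
        conditions = {"PEP1": 0.0, "PEP2": 30.0, "PEP3": 120.0}
    rng = _rng(seed, "elispot")
    rows = []
    for rep in range(1, n_replicates + 1):
        lam = nc_rate * cells_per_well / 1e6
        rows.append({"condition": "NC", "donor": donor, "replicate": rep,
                     "spots": int(rng.poisson(lam)), "cells_plated": cells_per_well})
    expected = {}
    for cond, effect in conditions.items():
        if effect < 0:
            raise ValueError("effects must be >= 0")
        rate = nc_rate + effect
        for rep in range(1, n_replicates + 1):
            lam = rate * cells_per_well / 1e6
            rows.append({"condition": cond, "donor": donor, "replicate": rep,
                         "spots": int(rng.poisson(lam)), "cells_plated": cells_per_well})
        expected[cond] = bool(rate > rate_min and rate >= fold_min * max(nc_rate, 1.0))
    truth = {"seed": seed, "nc_rate": nc_rate, "conditions": conditions,
             "expected_positive": expected}
    return pd.DataFrame(rows), truth


def gen_repertoire(
    seed: int,
    donors: tuple[str, ...] = ("D1", "D2"),
    n_cells: int = 4000,
    n_clonotypes: int = 500,
    n_expanded: int = 15,
    expansion_boost: float = 30.0,
    state_mixture: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell clonotype table with planted stimulation-expanded clonotypes.

    Baseline clonotype frequencies are power-law and condition-agnostic
    (expansion driven by the shared cytokine media, visible in both
    stimulated and non-stimulated samples). Planted clonotypes model
    antigen-specific responses: with ``expansion_boost`` > 1 they occur
    only in stimulated samples, with frequency boosted ``expansion_boost``-
    fold over their baseline rank frequency, and their cells are
    preferentially active/exhausted; at ``expansion_boost`` == 1 the plant
    is inert (planted ids behave like background). Naive cells draw
    near-unique clonotypes, so the naive population shows essentially no
    expansion.
    """
    if state_mixture is None:
        state_mixture = {"active": 0.25, "exhausted": 0.35, "naive": 0.35, "other": 0.05}
    if abs(sum(state_mixture.values()) - 1.0) > 1e-9:
        raise ValueError("state_mixture must sum to 1")
    if expansion_boost < 1:
        raise ValueError("expansion_boost must be >= 1")
    rng = _rng(seed, "repertoire")
    base = 1.0 / np.arange(1, n_clonotypes + 1) ** 1.2  # power-law frequencies
    base /= base.sum()
    names = [f"CT{i:04d}" for i in range(n_clonotypes)]
    # planted ids take mid-head ranks so they are well-populated
    planted_ranks = list(range(15, 15 + n_expanded))
    planted = [names[i] for i in planted_ranks]
    planted_mask = np.zeros(n_clonotypes, dtype=bool)
    planted_mask[planted_ranks] = True
    stim_freq = base * np.where(planted_mask, expansion_boost, 1.0)
    stim_freq /= stim_freq.sum()
    if expansion_boost > 1:
        nonstim_freq = np.where(planted_mask, 0.0, base)
        nonstim_freq /= nonstim_freq.sum()
    else:
        nonstim_freq = base
    cdr3a = {nm: "CA" + _random_aa(rng, 8) + "F" for nm in names}
    cdr3b = {nm: "CASS" + _random_aa(rng, 7) + "F" for nm in names}
    states = list(state_mixture)
    state_p = np.array([state_mixture[s] for s in states])
    # planted cells skew toward antigen-experienced states
    planted_state_p = np.array(
        [{"active": 0.55, "exhausted": 0.4}.get(s, 0.05 / max(1, len(states) - 2))
         for s in states]
    )
    planted_state_p /= planted_state_p.sum()
    rows = []
    for cell in range(n_cells):
        donor = donors[cell % len(donors)]
        condition = "stimulated" if rng.random() < 0.5 else "nonstimulated"
        state = str(rng.choice(states, p=state_p))
        if state == "naive":
            a = "CA" + _random_aa(rng, 9) + "F"
            b = "CASS" + _random_aa(rng, 8) + "F"
        else:
            freq = stim_freq if condition == "stimulated" else nonstim_freq
            nm = names[int(rng.choice(n_clonotypes, p=freq))]
            if nm in planted:
                state = str(rng.choice(states, p=planted_state_p))
            a, b = cdr3a[nm], cdr3b[nm]
        rows.append({
            "barcode": f"BC{cell:06d}", "donor": donor, "condition": condition,
            "cell_state": state, "cdr3a": a, "cdr3b": b,
        })
    truth = {
        "seed": seed,
        "planted_expanded": sorted(f"{cdr3a[nm]}_{cdr3b[nm]}" for nm in planted),
        "state_mixture": state_mixture,
        "expansion_boost": expansion_boost,
    }
    return pd.DataFrame(rows), truth


def gen_cdr3_sets(
    seed: int,
    n_pos: int = 30,
    n_neg: int = 30,
    core_length: int = 9,
    motif_positions: dict[int, str] | None = None,
    glycine_positions: tuple[int, ...] = (3,),
    motif_rate: float = 0.9,
    base_rate: float = 0.4,
    base_rate2: float = 0.3,
    length_jitter: int = 4,
) -> tuple[CDR3Set, CDR3Set, dict]:
    """CDR3 sets sharing a base motif, with planted divergent positions.

    Both sets carry a common base motif — at every non-divergent core
    position a primary and a secondary preferred residue drawn with
    probabilities ``base_rate`` and ``base_rate2`` — emulating the
    conserved chemistry classes of CDR3 loops; this shared structure is
    what makes non-divergent positions correlate between the two sets'
    PSSMs. At the divergent positions the positive set carries its planted
    residue (glycine at ``glycine_positions``) with probability
    ``motif_rate`` while the negative set is uniform there: naive
    repertoires have no preference at the positions where antigen-driven
    clones converge, so those positions show no correlation. Random flanks
    of 0..``length_jitter`` residues are added on each side; truth records
    the planted left-flank offsets and the divergent positions.
    """
    if motif_positions is None:
        motif_positions = {6: "W"}
    for p in list(motif_positions) + list(glycine_positions):
        if not 1 <= p <= core_length:
            raise ValueError("motif positions must lie within the core")
    plan = dict(motif_positions)
    for p in glycine_positions:
        plan[p] = "G"
    rng = _rng(seed, "cdr3_sets")
    # shared primary/secondary base preference at non-divergent positions only
    base_pref = {}
    for p in range(1, core_length + 1):
        if p not in plan:
            picks = rng.choice(list(AA20), size=2, replace=False)
            base_pref[p] = (str(picks[0]), str(picks[1]))

    def make_core(planted: bool) -> str:
        core = []
        for p in range(1, core_length + 1):
            if p in plan:
                if planted and rng.random() < motif_rate:
                    core.append(plan[p])
                else:
                    core.append(str(rng.choice(list(AA20))))
            else:
                u = rng.random()
                if u < base_rate:
                    core.append(base_pref[p][0])
                elif u < base_rate + base_rate2:
                    core.append(base_pref[p][1])
                else:
                    core.append(str(rng.choice(list(AA20))))
        return "".join(core)

    def flank(seq: str, bare: bool) -> tuple[str, int]:
        # the first sequence of each set is unflanked, so the smallest
        # sequence length equals the core length (the core-size rule)
        if bare:
            return seq, 0
        left = int(rng.integers(0, length_jitter + 1))
        right = int(rng.integers(0, length_jitter + 1))
        return _random_aa(rng, left) + seq + _random_aa(rng, right), left

    pos_seqs, pos_offsets = [], []
    for i in range(n_pos):
        s, off = flank(make_core(True), bare=(i == 0))
        pos_seqs.append(s)
        pos_offsets.append(off)
    neg_seqs, neg_offsets = [], []
    for i in range(n_neg):
        s, off = flank(make_core(False), bare=(i == 0))
        neg_seqs.append(s)
        neg_offsets.append(off)
    truth = {
        "seed": seed,
        "core_length": core_length,
        "planted_residues": {str(p): r for p, r in sorted(plan.items())},
        "base_preferences": {str(p): list(r) for p, r in sorted(base_pref.items())},
        "divergent_positions": sorted(plan),
        "glycine_positions": list(glycine_positions),
        "motif_rate": motif_rate,
        "base_rate": base_rate,
        "positive_offsets": pos_offsets,
        "negative_offsets": neg_offsets,
    }
    return (
        CDR3Set("positive", tuple(pos_seqs)),
        CDR3Set("negative", tuple(neg_seqs)),
        truth,
    )


def gen_caller_tables(
    seed: int,
    cohort_size: int = 10,
    callers: tuple[str, ...] = ("callerA", "callerB", "callerC", "callerD"),
    n_true: int = 20,
    n_shared_with_normal: int = 5,
    n_partial_caller: int = 5,
    n_spanning_only: int = 5,
    caller_sensitivity: float = 1.0,
    actionable_fraction: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Fusion-caller tables with planted positives and three background classes.

    True fusions appear in tumors only, from every caller, with split-read
    support. Background classes: fusions shared with adjacent normals,
    fusions reported by only a subset of callers, and fusions with
    spanning-only support. ``caller_sensitivity`` < 1 makes each non-first
    caller miss true fusions independently. Truth lists the planted
    positives and an actionable-gene list covering ``actionable_fraction``
    of them.
    """
    rng = _rng(seed, "caller_tables")
    used = set()

    def gene_pair(tag, i):
        pair = (f"{tag}{i:03d}A", f"{tag}{i:03d}B")
        used.add(pair)
        return pair

    rows = []
    true_pairs, samples_of, called_by = [], {}, {}
    for i in range(n_true):
        g5, g3 = gene_pair("TRU", i)
        sample = f"T{int(rng.integers(0, cohort_size)):02d}"
        true_pairs.append((g5, g3))
        samples_of[(g5, g3)] = sample
        called_by[(g5, g3)] = []
        for ci, caller in enumerate(callers):
            if ci > 0 and rng.random() > caller_sensitivity:
                continue
            called_by[(g5, g3)].append(caller)
            rows.append({"sample_id": sample, "tissue": "tumor", "caller": caller,
                         "gene5": g5, "gene3": g3,
                         "split_reads": int(rng.integers(2, 40)),
                         "spanning_reads": int(rng.integers(0, 30))})
    for i in range(n_shared_with_normal):
        g5, g3 = gene_pair("SHR", i)
        sample = f"T{int(rng.integers(0, cohort_size)):02d}"
        for caller in callers:
            rows.append({"sample_id": sample, "tissue": "tumor", "caller": caller,
                         "gene5": g5, "gene3": g3,
                         "split_reads": int(rng.integers(2, 40)),
                         "spanning_reads": int(rng.integers(0, 30))})
        rows.append({"sample_id": f"N{int(rng.integers(0, cohort_size)):02d}",
                     "tissue": "normal", "caller": str(rng.choice(callers)),
                     "gene5": g5, "gene3": g3,
                     "split_reads": int(rng.integers(1, 10)),
                     "spanning_reads": int(rng.integers(0, 10))})
    for i in range(n_partial_caller):
        g5, g3 = gene_pair("PRT", i)
        sample = f"T{int(rng.integers(0, cohort_size)):02d}"
        subset = rng.choice(callers, size=len(callers) - 1, replace=False)
        for caller in subset:
            rows.append({"sample_id": sample, "tissue": "tumor", "caller": str(caller),
                         "gene5": g5, "gene3": g3,
                         "split_reads": int(rng.integers(2, 40)),
                         "spanning_reads": int(rng.integers(0, 30))})
    for i in range(n_spanning_only):
        g5, g3 = gene_pair("SPN", i)
        sample = f"T{int(rng.integers(0, cohort_size)):02d}"
        for caller in callers:
            rows.append({"sample_id": sample, "tissue": "tumor", "caller": caller,
                         "gene5": g5, "gene3": g3,
                         "split_reads": 0,
                         "spanning_reads": int(rng.integers(5, 60))})
    n_actionable = max(1, int(round(actionable_fraction * n_true)))
    actionable = sorted({true_pairs[i][1] for i in range(n_actionable)})
    # a fusion missed by any caller cannot survive the strict intersection
    expected = [
        [g5, g3, samples_of[(g5, g3)]]
        for (g5, g3) in true_pairs
        if len(called_by[(g5, g3)]) == len(callers) and g3 in actionable
    ]
    truth = {
        "seed": seed,
        "planted_true_fusions": sorted(
            [g5, g3, samples_of[(g5, g3)]] for (g5, g3) in true_pairs
        ),
        "expected_positive_hits": sorted(expected),
        "actionable_genes": actionable,
        "callers": list(callers),
    }
    return pd.DataFrame(rows), truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
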