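"""Chimeric (fusion) transcript assembly, ORF enumeration, and in-silico PCR.

A gene fusion joins the 5' exons of one gene to the 3' exons of another
(e.g. a chromosomal inversion joining KIF5B exons 1-15 to RET exons 12-19).
This module builds the chimeric nucleotide sequence from the two parent
segments, enumerates ATG-initiated open reading frames on the sense strand,
maps the nucleotide breakpoint into protein coordinates, and checks primer
pairs by exact-match in-silico PCR.

Coordinates are 0-based half-open internally; human-facing reports are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

NT_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class GeneSegment:
    """One parent gene's contribution to a fusion transcript."""

    gene_symbol: str
    role: str  # "five_prime" | "three_prime"
    sequence: str
    exon_span_label: str = ""

    def __post_init__(self):
        if self.role not in ("five_prime", "three_prime"):
            raise ValueError(f"unknown segment role {self.role!r}")
        _validate_nt(self.sequence, what=f"{self.role} segment ({self.gene_symbol})")


@dataclass(frozen=True)
class FusionTranscript:
    """Chimeric transcript: 5'-parent sequence followed by 3'-parent sequence.

    ``breakpoint`` is the 0-based offset of the junction, equal to the length
    of the 5' segment, so ``sequence[:breakpoint]`` is 5'-parent derived.
    """

    sequence: str
    breakpoint: int
    parents: tuple[str, str]

    def __post_init__(self):
        if not (0 < self.breakpoint < len(self.sequence)):
            raise ValueError(
                f"breakpoint {self.breakpoint} outside (0, {len(self.sequence)})"
            )


@dataclass(frozen=True)
class OpenReadingFrame:
    frame: int
    nt_start: int
    nt_end: int  # half-open; includes the terminating stop codon if present
    protein: str  # no terminal stop symbol
    spans_junction: bool
    in_frame_with_junction: bool
    has_stop: bool = True


@dataclass(frozen=True)
class Amplicon:
    start: int
    end: int  # half-open template interval, both primer footprints included
    length_bp: int
    fwd_match_strand: str = "plus"
    rev_match_strand: str = "minus"


def _validate_nt(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty {what}")
    for i, c in enumerate(seq):
        if c not in NT_ALPHABET:
            raise ValueError(f"invalid character {c!r} at position {i} in {what}")


def build_fusion_transcript(seg5: GeneSegment, seg3: GeneSegment) -> FusionTranscript:
    """Concatenate the 5' and 3' parent segments into a fusion transcript.

    The breakpoint offset equals the 5'-segment length.
    """
    if seg5.role != "five_prime" or seg3.role != "three_prime":
        raise ValueError("segments must be passed as (five_prime, three_prime)")
    return FusionTranscript(
        sequence=seg5.sequence + seg3.sequence,
        breakpoint=len(seg5.sequence),
        parents=(seg5.gene_symbol, seg3.gene_symbol),
    )


def translate(nt: str) -> str:
    """Standard-code translation; stops rendered '*', N-containing codons 'X'.

    Length must be a multiple of 3.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} not divisible by 3")
    if not nt:
        return ""
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def enumerate_orfs(
    transcript: FusionTranscript,
    min_aa: int = 25,
    require_stop: bool = False,
) -> list[OpenReadingFrame]:
    """Enumerate ATG-initiated sense-strand ORFs in all three frames.

    One ORF is reported per (frame, terminating stop) group: the longest
    ATG-initiated one. Each ORF ends at its first in-frame stop codon
    (included in the nt interval but not in the protein); when
    ``require_stop`` is false an ORF may run off the 3' end. Output is
    sorted by protein length descending, ties by nt_start ascending.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.sequence
    bp = transcript.breakpoint
    orfs: list[OpenReadingFrame] = []
    for frame in range(3):
        # earliest ATG per stop group wins (longest ORF for that stop)
        start: Optional[int] = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if start is None and codon == START_CODON:
                start = i
            elif start is not None and codon in STOP_CODONS:
                orfs.append(_make_orf(seq, bp, frame, start, i + 3, has_stop=True))
                start = None
            i += 3
        if start is not None and not require_stop:
            end = start + 3 * ((len(seq) - start) // 3)
            orfs.append(_make_orf(seq, bp, frame, start, end, has_stop=False))
    orfs = [o for o in orfs if len(o.protein) >= min_aa]
    orfs.sort(key=lambda o: (-len(o.protein), o.nt_start))
    return orfs


def _make_orf(
    seq: str, breakpoint: int, frame: int, start: int, end: int, has_stop: bool
) -> OpenReadingFrame:
    prot = translate(seq[start:end])
    if has_stop:
        prot = prot[:-1]
    spans = start < breakpoint < end
    return OpenReadingFrame(
        frame=frame,
        nt_start=start,
        nt_end=end,
        protein=prot,
        spans_junction=spans,
        in_frame_with_junction=spans and (breakpoint - start) % 3 == 0,
        has_stop=has_stop,
    )


def junction_protein_index(
    orf: OpenReadingFrame, transcript: FusionTranscript
) -> Optional[int]:
    """Number of complete ORF codons lying fully 5' of the breakpoint.

    ``protein[:j]`` is then encoded entirely by the 5' parent; a codon split
    by the breakpoint is assigned to the 3' side. Returns None for ORFs that
    do not span the junction.
    """
    if not orf.spans_junction:
        return None
    return (transcript.breakpoint - orf.nt_start) // 3


def revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def insilico_pcr(template: str, fwd: str, rev: str) -> list[Amplicon]:
    """Exact-match PCR: forward primer on the plus strand, reverse on minus.

    For each forward-primer site, the nearest downstream reverse-primer site
    whose footprint starts at or after the end of the forward footprint
    yields one amplicon; the amplicon length includes both primer footprints.
    An empty list means no amplification.
    """
    for name, p in (("forward", fwd), ("reverse", rev)):
        if len(p) < 10:
            raise ValueError(f"{name} primer shorter than 10 nt")
        for c in p:
            if c not in "ACGT":
                raise ValueError(f"degenerate/invalid base {c!r} in {name} primer")
    _validate_nt(template, what="template")
    rc = revcomp(rev)
    fwd_sites = _find_all(template, fwd)
    rev_sites = _find_all(template, rc)
    amps: list[Amplicon] = []
    for i in fwd_sites:
        downstream = [j for j in rev_sites if j >= i + len(fwd)]
        if downstream:
            j = min(downstream)
            end = j + len(rc)
            amps.append(Amplicon(start=i, end=end, length_bp=end - i))
    return amps


def _find_all(haystack: str, needle: str) -> list[int]:
    sites, i = [], haystack.find(needle)
    while i != -1:
        sites.append(i)
        i = haystack.find(needle, i + 1)
    return sites


# ---------------------------------------------------------------------------
# FASTA I/O. Fusion-transcript headers carry the breakpoint as "bp=<int>".

def write_fusion_fasta(transcript: FusionTranscript, path) -> None:
    name = f"{transcript.parents[0]}--{transcript.parents[1]}"
    rec = SeqRecord(
        Seq(transcript.sequence), id=name, description=f"bp={transcript.breakpoint}"
    )
    SeqIO.write([rec], path, "fasta")


def read_fusion_fasta(path) -> FusionTranscript:
    rec = next(SeqIO.parse(path, "fasta"))
    bp = None
    for tok in rec.description.split():
        if tok.startswith("bp="):
            bp = int(tok[3:])
    if bp is None:
        raise ValueError(f"no bp=<int> token in FASTA header of {path}")
    parents = tuple(rec.id.split("--")) if "--" in rec.id else (rec.id, rec.id)
    return FusionTranscript(sequence=str(rec.seq).upper(), breakpoint=bp,
                            parents=(parents[0], parents[-1]))


def read_segment_fasta(path, role: str) -> GeneSegment:
    rec = next(SeqIO.parse(path, "fasta"))
    return GeneSegment(
        gene_symbol=rec.id, role=role, sequence=str(rec.seq).upper(),
        exon_span_label=rec.description[len(rec.id):].strip(),
    )


def orf_report(orfs: Iterable[OpenReadingFrame], transcript: FusionTranscript):
    """ORF table with 1-based inclusive coordinates (human-facing)."""
    import pandas as pd

    rows = []
    for o in orfs:
        rows.append(
            {
                "frame": o.frame,
                "nt_start": o.nt_start + 1,
                "nt_end": o.nt_end,
                "aa_len": len(o.protein),
                "spans_junction": o.spans_junction,
                "in_frame_with_junction": o.in_frame_with_junction,
                "junction_protein_index": junction_protein_index(o, transcript),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "nt_start", "nt_end", "aa_len", "spans_junction",
            "in_frame_with_junction", "junction_protein_index",
        ],
    )
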