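"""Fusion transcript assembly, ORF enumeration, translation, in-silico PCR."""

import numpy as np
import pytest

from fusionpept.chimera import (
    Amplicon,
    FusionTranscript,
    GeneSegment,
    build_fusion_transcript,
    enumerate_orfs,
    insilico_pcr,
    junction_protein_index,
    read_fusion_fasta,
    revcomp,
    translate,
    write_fusion_fasta,
)

STOPS = {"TAA", "TAG", "TGA"}


def orf_scan_oracle(seq, min_aa=1, require_stop=False):
    """Exhaustive reference: scan every position for ATG, extend to first stop.

    Keeps one ORF per (frame, stop) group: the longest (earliest ATG).
    """
    found = {}
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = None
        for i in range(start, len(seq) - 2, 3):
            if seq[i : i + 3] in STOPS:
                end = i + 3
                break
        if end is None:
            if require_stop:
                continue
            end = start + 3 * ((len(seq) - start) // 3)
            key = (start % 3, "end")
        else:
            key = (start % 3, end)
        if key not in found or start < found[key][0]:
            found[key] = (start, end)
    out = set()
    for frame_key, (start, end) in found.items():
        stop_terminated = frame_key[1] != "end" or seq[end - 3 : end] in STOPS
        n_aa = (end - start) // 3 - (1 if seq[end - 3 : end] in STOPS else 0)
        if n_aa >= min_aa:
            out.add((start, end))
    return out


def seg(s, role="five_prime", name="G"):
    return GeneSegment(name, role, s)


class TestBuildFusion:
    def test_concatenation_and_breakpoint(self):
        tx = build_fusion_transcript(seg("ATG"), seg("TAA", "three_prime"))
        assert tx.sequence == "ATGTAA"
        assert tx.breakpoint == 3

    def test_length_additivity(self, rng):
        s5 = "".join(rng.choice(list("ACGT"), 100))
        s3 = "".join(rng.choice(list("ACGT"), 50))
        tx = build_fusion_transcript(seg(s5), seg(s3, "three_prime"))
        assert len(tx.sequence) == 150 and tx.breakpoint == 100

    def test_breakpoint_invariant_under_3prime_extension(self):
        tx1 = build_fusion_transcript(seg("ACGTACGT"), seg("TTTT", "three_prime"))
        tx2 = build_fusion_transcript(seg("ACGTACGT"), seg("TTTTCCCC", "three_prime"))
        assert tx1.breakpoint == tx2.breakpoint == 8

    def test_empty_segment_rejected_naming_role(self):
        with pytest.raises(ValueError, match="three_prime"):
            seg("", "three_prime")

    def test_invalid_character_rejected_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            seg("ACXGT")


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,aa",
        [
            ("ATG", "M"),
            ("ATGTAA", "M*"),
            ("AATAATGACGTAAAA", "NNDVK"),
            ("ATGNNN", "MX"),
            ("", ""),
        ],
    )
    def test_examples(self, nt, aa):
        assert translate(nt) == aa

    def test_codon_table_oracle(self, rng):
        from Bio.Seq import Seq

        for _ in range(50):
            nt = "".join(rng.choice(list("ACGT"), 30))
            assert translate(nt) == str(Seq(nt).translate())

    def test_partial_codon_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            translate("ATGA")


class TestEnumerateOrfs:
    def test_no_start_codon(self):
        tx = FusionTranscript("CCCCCC", 3, ("A", "B"))
        assert enumerate_orfs(tx, min_aa=1) == []

    def test_hand_translatable(self):
        tx = FusionTranscript("ATGAAATGA", 4, ("A", "B"))
        orfs = enumerate_orfs(tx, min_aa=2)
        assert len(orfs) == 1
        (o,) = orfs
        assert o.protein == "MK"
        assert o.nt_start == 0 and o.nt_end == 9
        assert o.spans_junction  # breakpoint 4 inside [0, 9)

    def test_against_exhaustive_scan_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(30, 1000))
            s = "".join(rng.choice(list("ACGT"), n))
            tx = FusionTranscript(s, n // 2, ("A", "B"))
            got = {(o.nt_start, o.nt_end) for o in enumerate_orfs(tx, min_aa=1)}
            assert got == orf_scan_oracle(s, min_aa=1)

    def test_require_stop_drops_runoff_orfs(self):
        tx = FusionTranscript("ATGAAAAAA", 3, ("A", "B"))
        assert enumerate_orfs(tx, min_aa=1, require_stop=True) == []
        orfs = enumerate_orfs(tx, min_aa=1, require_stop=False)
        assert len(orfs) == 1 and orfs[0].protein == "MKK"

    def test_sorted_by_length_then_start(self, fusion_dataset):
        *_, tx, _ = fusion_dataset
        orfs = enumerate_orfs(tx, min_aa=1)
        lens = [len(o.protein) for o in orfs]
        assert lens == sorted(lens, reverse=True)

    def test_orf_invariants(self, fusion_dataset):
        *_, tx, _ = fusion_dataset
        for o in enumerate_orfs(tx, min_aa=1):
            assert (o.nt_end - o.nt_start) % 3 == 0
            assert o.nt_start % 3 == o.frame
            n_codons = (o.nt_end - o.nt_start) // 3
            assert len(o.protein) in (n_codons, n_codons - 1)


class TestJunctionProteinIndex:
    def test_complete_codons(self):
        tx = FusionTranscript("ATG" + "AAA" * 9, 15, ("A", "B"))
        (o,) = enumerate_orfs(tx, min_aa=1)
        assert junction_protein_index(o, tx) == 5

    def test_split_codon_goes_to_three_prime(self):
        # ORF starting at 2, breakpoint 10: floor((10-2)/3) = 2
        s = "CC" + "ATG" + "AAA" * 5 + "TGA"
        tx = FusionTranscript(s, 10, ("A", "B"))
        orf = next(o for o in enumerate_orfs(tx, min_aa=1) if o.nt_start == 2)
        assert junction_protein_index(orf, tx) == 2

    def test_non_spanning_returns_none(self):
        tx = FusionTranscript("CCCATGAAATGA", 2, ("A", "B"))
        orf = next(o for o in enumerate_orfs(tx, min_aa=1) if o.nt_start == 3)
        assert not orf.spans_junction
        assert junction_protein_index(orf, tx) is None

    def test_five_prime_half_translates_from_parent_alone(self, fusion_dataset):
        seg5, _, tx, _ = fusion_dataset
        for o in enumerate_orfs(tx, min_aa=10):
            if not o.spans_junction:
                continue
            j = junction_protein_index(o, tx)
            prefix = translate(tx.sequence[o.nt_start : o.nt_start + 3 * j])
            parent = translate(
                seg5.sequence[o.nt_start : o.nt_start + 3 * ((len(seg5.sequence) - o.nt_start) // 3)]
            )
            assert parent.startswith(prefix)


class TestInsilicoPcr:
    FWD = "GATCGATCGATCGATCGATCGAT"  # 23-mer
    REV = "CCGGAACCGGTTAACCGGTAA"  # 21-mer

    def test_no_forward_site_no_amplification(self):
        assert insilico_pcr("ACGT" * 30, self.FWD, self.REV) == []

    def test_constructed_amplicon_length(self):
        template = self.FWD + "AAAA" + revcomp(self.REV)
        amps = insilico_pcr(template, self.FWD, self.REV)
        assert len(amps) == 1
        assert amps[0].length_bp == 23 + 4 + 21 == len(template)
        assert (amps[0].start, amps[0].end) == (0, len(template))

    def test_reverse_complement_symmetry(self, rng):
        for _ in range(20):
            mid = "".join(rng.choice(list("ACGT"), int(rng.integers(0, 50))))
            template = "TT" + self.FWD + mid + revcomp(self.REV) + "GG"
            fwd_lens = [a.length_bp for a in insilico_pcr(template, self.FWD, self.REV)]
            swapped = [a.length_bp for a in insilico_pcr(revcomp(template), self.REV, self.FWD)]
            assert fwd_lens == swapped

    def test_planted_primer_distance(self, rng):
        from fusionpept import simulate

        seg5, seg3, truth = simulate.gen_fusion_pair(
            7, fwd_primer=self.FWD, rev_primer=self.REV
        )
        tx = build_fusion_transcript(seg5, seg3)
        amps = insilico_pcr(tx.sequence, self.FWD, self.REV)
        assert [a.length_bp for a in amps] == [truth["amplicon_length"]]
        # non-fusion control: the 3' parent alone lacks the forward site
        assert insilico_pcr(seg3.sequence, self.FWD, self.REV) == []

    def test_degenerate_primer_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            insilico_pcr("ACGT" * 20, "ATGNATGCATGCA", self.REV)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            insilico_pcr("ACGT" * 20, "ATGCATGC", self.REV)


def test_fusion_fasta_roundtrip(tmp_path, fusion_dataset):
    *_, tx, _ = fusion_dataset
    p = tmp_path / "fusion.fasta"
    write_fusion_fasta(tx, p)
    back = read_fusion_fasta(p)
    assert back.sequence == tx.sequence
    assert back.breakpoint == tx.breakpoint
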