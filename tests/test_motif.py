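"""Gibbs core alignment, PSSM construction, PBPC, pairwise alignment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fusionpept import simulate
from fusionpept.motif import (
    AA20,
    AA_INDEX,
    CDR3Set,
    build_pssm,
    gibbs_core_align,
    glycine_conservation_report,
    pairwise_identity_similarity,
    pbpc,
    total_alignment_score,
)


def oracle_loo_score(seqs, offsets, L, pc=20.0):
    """Independent reference for the leave-one-out alignment objective."""
    cores = [s[o : o + L] for s, o in zip(seqs, offsets)]
    n = len(cores)
    total = 0.0
    for i, core in enumerate(cores):
        others = cores[:i] + cores[i + 1 :]
        for p, a in enumerate(core):
            c = sum(1 for o in others if o[p] == a)
            total += math.log2((c + pc * 0.05) / ((n - 1 + pc) * 0.05))
    return total


def oracle_best(seqs, L, pc=20.0):
    best = -np.inf
    for combo in itertools.product(*[range(len(s) - L + 1) for s in seqs]):
        sc = oracle_loo_score(seqs, combo, L, pc)
        best = max(best, sc)
    return best


class TestBuildPssm:
    def test_hand_arithmetic_single_core(self):
        pssm = build_pssm(["AAAA"], pseudocount=1.0)
        a = AA_INDEX["A"]
        expected_a = math.log2((1 + 0.05) / ((1 + 1) * 0.05))
        expected_other = math.log2(0.05 / 0.1)
        for p in range(4):
            assert pssm.matrix[p, a] == pytest.approx(expected_a)
            assert pssm.matrix[p, (a + 1) % 20] == pytest.approx(expected_other)

    def test_background_matching_counts_give_zero(self):
        # one core per residue: counts == N * background exactly
        cores = [a * 5 for a in AA20]
        pssm = build_pssm(cores, pseudocount=1.0)
        assert np.allclose(pssm.matrix, 0.0)

    def test_frequency_invariance_small_pseudocount(self):
        # doubling every core leaves estimated frequencies (2^matrix * bg)
        # unchanged in the pseudocount -> 0 limit
        cores = ["ACDE", "ACDE", "AGDE"]
        f1 = np.exp2(build_pssm(cores, pseudocount=1e-9).matrix)
        f2 = np.exp2(build_pssm(cores * 2, pseudocount=1e-9).matrix)
        assert np.allclose(f1, f2, atol=1e-6)

    def test_empty_cores_error(self):
        with pytest.raises(ValueError):
            build_pssm([])

    def test_finite_everywhere(self):
        pssm = build_pssm(["AC", "WY"], pseudocount=0.5)
        assert np.all(np.isfinite(pssm.matrix))


class TestGibbsCoreAlign:
    def test_forced_alignment_identical_sequences(self):
        seqs = ["ACDEF"] * 6
        offsets, pssm = gibbs_core_align(seqs, core_length=5, seed=0)
        assert offsets == [0] * 6
        # point-mass columns smoothed by pseudocount
        for p, a in enumerate("ACDEF"):
            assert pssm.matrix[p].argmax() == AA_INDEX[a]

    def test_matches_exhaustive_oracle_on_small_instances(self, rng):
        for trial in range(10):
            n = int(rng.integers(3, 6))
            L = int(rng.integers(3, 6))
            seqs = [
                "".join(rng.choice(list(AA20), L + int(rng.integers(0, 3))))
                for _ in range(n)
            ]
            offsets, _ = gibbs_core_align(seqs, core_length=L, seed=trial)
            got = total_alignment_score(seqs, offsets, L)
            assert got >= oracle_best(seqs, L) - 1e-6

    def test_planted_offset_recovery(self):
        pos, _, truth = simulate.gen_cdr3_sets(31)
        offsets, _ = gibbs_core_align(pos, core_length=truth["core_length"], seed=31)
        recovered = np.mean(
            [o == t for o, t in zip(offsets, truth["positive_offsets"])]
        )
        assert recovered >= 0.9

    def test_deterministic_given_seed(self):
        pos, _, _ = simulate.gen_cdr3_sets(4, n_pos=12)
        o1, p1 = gibbs_core_align(pos, seed=9, iterations=300)
        o2, p2 = gibbs_core_align(pos, seed=9, iterations=300)
        assert o1 == o2
        assert np.array_equal(p1.matrix, p2.matrix)

    def test_core_longer_than_sequence_errors(self):
        with pytest.raises(ValueError, match="ACD"):
            gibbs_core_align(["ACDEFGH", "ACD"], core_length=5)


class TestPbpc:
    def test_self_correlation_all_one_nothing_flagged(self):
        pssm = build_pssm(["ACDEFGHIK", "ACDEFGHIR", "ACWEFGHIK"])
        res = pbpc(pssm, pssm)
        assert np.allclose(res.r, 1.0)
        assert not res.flagged.any()

    def test_negated_column_significant_anticorrelation_not_flagged(self):
        pssm_pos = build_pssm(["ACDEFGHIK"] * 3 + ["PCDEFGHIK"] * 2)
        neg_matrix = pssm_pos.matrix.copy()
        neg_matrix[0] = -neg_matrix[0]
        import dataclasses

        pssm_neg = dataclasses.replace(pssm_pos, matrix=neg_matrix)
        res = pbpc(pssm_pos, pssm_neg)
        assert res.r[0] == pytest.approx(-1.0)
        assert not res.flagged[0]  # two-sided test: anti-correlation is significant

    def test_degenerate_column_flagged_with_p_one(self):
        import dataclasses

        pssm_pos = build_pssm(["ACDEF", "GHIKL", "MNPQR"])
        flat = pssm_pos.matrix.copy()
        flat[2] = 0.0
        pssm_neg = dataclasses.replace(pssm_pos, matrix=flat)
        res = pbpc(pssm_pos, pssm_neg)
        assert res.degenerate[2]
        assert res.p_value[2] == 1.0
        assert res.flagged[2]

    def test_core_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pbpc(build_pssm(["ACDEF"]), build_pssm(["ACDE"]))

    def test_null_flag_rate_matches_t18(self, rng):
        """Independent random score columns flag at the analytic null rate.

        Under independence, the Pearson p-value is uniform, so the flag rate
        P(p >= 0.05) is 0.95; checked against 10,000 simulated pairs within
        Monte-Carlo error, and the t(18) transform is cross-checked directly.
        """
        n_pairs = 10_000
        x = rng.standard_normal((n_pairs, 20))
        y = rng.standard_normal((n_pairs, 20))
        flags = 0
        for i in range(n_pairs):
            r, p = stats.pearsonr(x[i], y[i])
            flags += p >= 0.05
            if i < 100:  # spot-check the t(18) closed form
                t = r * math.sqrt(18 / (1 - r * r))
                p_t = 2 * stats.t.sf(abs(t), df=18)
                assert p == pytest.approx(p_t, rel=1e-6)
        rate = flags / n_pairs
        assert abs(rate - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n_pairs)

    def test_flag_recovery_on_planted_sets(self):
        """Planted divergent positions are flagged; shared positions are not."""
        hits = 0
        runs = 10
        for seed in range(runs):
            pos, neg, truth = simulate.gen_cdr3_sets(seed + 200)
            L = truth["core_length"]
            _, pssm_p = gibbs_core_align(pos, core_length=L, seed=seed, n_restarts=2)
            _, pssm_n = gibbs_core_align(neg, core_length=L, seed=seed, n_restarts=2)
            res = pbpc(pssm_p, pssm_n)
            flagged = set(res.flagged_positions)
            planted = set(truth["divergent_positions"])
            hits += planted <= flagged and len(flagged - planted) <= 1
        assert hits >= 0.9 * runs


class TestPairwiseIdentitySimilarity:
    def test_identical_sequences(self):
        ident, simil = pairwise_identity_similarity(["ACDEFG", "ACDEFG"])
        assert ident[0, 1] == 100.0 and simil[0, 1] == 100.0

    def test_single_substitution(self):
        ident, simil = pairwise_identity_similarity(["ACDE", "ACDF"])
        assert ident[0, 1] == pytest.approx(75.0)
        # E/F scores negative under BLOSUM62: not a similarity either
        assert simil[0, 1] == pytest.approx(75.0)

    def test_conservative_substitution_counts_as_similar(self):
        # I/L scores +2 under BLOSUM62
        ident, simil = pairwise_identity_similarity(["ACDI", "ACDL"])
        assert ident[0, 1] == pytest.approx(75.0)
        assert simil[0, 1] == pytest.approx(100.0)

    def test_alignment_score_matches_dp_oracle(self, rng):
        """Global alignment score equals an independent linear-gap DP."""
        from Bio.Align import substitution_matrices, PairwiseAligner

        blosum = substitution_matrices.load("BLOSUM62")
        gap = -4.0

        def nw(a, b):
            m, n = len(a), len(b)
            D = np.zeros((m + 1, n + 1))
            D[:, 0] = gap * np.arange(m + 1)
            D[0, :] = gap * np.arange(n + 1)
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    D[i, j] = max(
                        D[i - 1, j - 1] + blosum[a[i - 1], b[j - 1]],
                        D[i - 1, j] + gap,
                        D[i, j - 1] + gap,
                    )
            return D[m, n]

        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = blosum
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        for _ in range(20):
            a = "".join(rng.choice(list(AA20), int(rng.integers(2, 7))))
            b = "".join(rng.choice(list(AA20), int(rng.integers(2, 7))))
            assert aligner.score(a, b) == pytest.approx(nw(a, b))

    def test_symmetry(self, rng):
        seqs = ["".join(rng.choice(list(AA20), 8)) for _ in range(4)]
        ident, simil = pairwise_identity_similarity(seqs)
        assert np.allclose(ident, ident.T)
        assert np.allclose(simil, simil.T)


class TestGlycineConservationReport:
    def test_planted_glycine_fraction(self):
        pos, _, truth = simulate.gen_cdr3_sets(77)
        L = truth["core_length"]
        report = glycine_conservation_report(
            list(pos.sequences), truth["positive_offsets"], L
        )
        for p in truth["glycine_positions"]:
            assert report.loc[p - 1, "glycine_fraction"] >= truth["motif_rate"] - 0.15

    def test_uniform_sequences_near_background(self, rng):
        seqs = ["".join(rng.choice(list(AA20), 9)) for _ in range(400)]
        report = glycine_conservation_report(seqs, [0] * 400, 9)
        assert np.all(np.abs(report["glycine_fraction"] - 0.05) < 0.05)

    def test_empty_flag_annotation(self):
        seqs = ["ACDEFGHIK"] * 5
        report = glycine_conservation_report(seqs, [0] * 5, 9)
        assert not report["flagged"].any()


def test_cdr3set_rejects_nonstandard_residues():
    with pytest.raises(ValueError):
        CDR3Set("positive", ("ACDEX",))
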