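"""CDR3 motif analysis: Gibbs core alignment, PSSMs, and position-based
Pearson correlation (PBPC).

Variable-length CDR3 amino-acid sequences are aligned to a fixed-length
core by single-cluster Gibbs sampling: each sequence gets an offset, and
offsets are resampled one sequence at a time against a position-specific
scoring matrix (PSSM) built from the remaining sequences, under a cooling
temperature schedule followed by a greedy refinement pass. The final cores
define a log-odds PSSM:

    M[p][a] = log2( (count_{p,a} + pc * bg_a) / ((N + pc) * bg_a) )

with additive pseudocount ``pc`` and background frequencies ``bg``
(default uniform 1/20).

PBPC compares the PSSMs of a response-positive set (e.g. top expanded
clonotypes) and a negative set (naive-only clonotypes): at each core
position the two 20-long log-odds columns are Pearson-correlated; the
two-sided p-value comes from the t statistic with n = 20 amino acids
(df = 18). Positions with p >= alpha are flagged "non-correlative" — the
positions where the two motifs genuinely differ. Note the test is
two-sided: strong anti-correlation at a position is significant
(not flagged) even though the motifs disagree there; flagged positions are
those with no detectable linear relationship.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from Bio import Align
from Bio.Align import substitution_matrices

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
UNIFORM_BG = np.full(20, 0.05)


@dataclass(frozen=True)
class CDR3Set:
    label: str  # "positive" | "negative"
    sequences: tuple[str, ...]
    chain: str = "beta"  # "alpha" | "beta"

    def __post_init__(self):
        for s in self.sequences:
            bad = set(s) - set(AA20)
            if bad:
                raise ValueError(f"non-standard residues {sorted(bad)} in {s!r}")

    @property
    def min_length(self) -> int:
        return min(len(s) for s in self.sequences)


@dataclass
class PSSM:
    core_length: int
    matrix: np.ndarray  # (L, 20) log2-odds
    pseudocount: float
    background: np.ndarray
    counts: Optional[np.ndarray] = None  # (L, 20) residue counts of the cores

    def __post_init__(self):
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite PSSM entries (pseudocount must be > 0)")


@dataclass(frozen=True)
class PBPCResult:
    r: np.ndarray  # per-position Pearson coefficient
    p_value: np.ndarray  # two-sided
    flagged: np.ndarray  # boolean; p >= alpha -> non-correlative position
    alpha: float
    degenerate: np.ndarray  # zero-variance positions (r undefined)

    @property
    def flagged_positions(self) -> list[int]:
        """1-based positions flagged as non-correlative."""
        return [int(i) + 1 for i in np.nonzero(self.flagged)[0]]


def build_pssm(
    cores: Sequence[str],
    pseudocount: float = 20.0,
    background: np.ndarray | None = None,
) -> PSSM:
    """Log-odds PSSM from equal-length cores with additive pseudocount."""
    if len(cores) == 0:
        raise ValueError("no cores to build a PSSM from")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    L = len(cores[0])
    if any(len(c) != L for c in cores):
        raise ValueError("cores must all have the same length")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((L, 20))
    for c in cores:
        for p, a in enumerate(c):
            counts[p, AA_INDEX[a]] += 1
    N = len(cores)
    matrix = np.log2((counts + pseudocount * bg) / ((N + pseudocount) * bg))
    return PSSM(core_length=L, matrix=matrix, pseudocount=pseudocount,
                background=bg, counts=counts)


def _score_sequence(core: str, counts: np.ndarray, n: int,
                    pseudocount: float, bg: np.ndarray) -> float:
    """Summed log-odds of one core against counts from the other sequences."""
    s = 0.0
    for p, a in enumerate(core):
        j = AA_INDEX[a]
        s += math.log2((counts[p, j] + pseudocount * bg[j]) / ((n + pseudocount) * bg[j]))
    return s


def total_alignment_score(
    seqs: Sequence[str], offsets: Sequence[int], core_length: int,
    pseudocount: float = 20.0, background: np.ndarray | None = None,
) -> float:
    """Leave-one-out summed log-odds of an offset assignment (higher = tighter motif)."""
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    cores = [s[o : o + core_length] for s, o in zip(seqs, offsets)]
    pssm = build_pssm(cores, pseudocount, bg)
    total = 0.0
    for i, c in enumerate(cores):
        counts = pssm.counts - _one_hot(c)
        total += _score_sequence(c, counts, len(cores) - 1, pseudocount, bg)
    return total


def _one_hot(core: str) -> np.ndarray:
    m = np.zeros((len(core), 20))
    for p, a in enumerate(core):
        m[p, AA_INDEX[a]] += 1
    return m


def gibbs_core_align(
    seqs: CDR3Set | Sequence[str],
    core_length: int | None = None,
    iterations: int | None = None,
    seed: int = 0,
    pseudocount: float = 20.0,
    background: np.ndarray | None = None,
    t_start: float = 1.5,
    t_end: float = 0.05,
    n_restarts: int = 5,
    exhaustive_limit: int = 5000,
) -> tuple[list[int], PSSM]:
    """Single-cluster Gibbs alignment of sequences to a fixed-length core.

    Each sequence i receives an offset in [0, len_i - core_length]. Sweeps
    resample one sequence at a time from the Boltzmann distribution over its
    offsets, scored against the leave-one-out PSSM, while the temperature
    anneals geometrically from ``t_start`` to ``t_end``; a final greedy pass
    moves every sequence to its argmax offset until no move improves. The
    chain is restarted ``n_restarts`` times from seeded initializations and
    the assignment with the highest total leave-one-out score wins. The
    default core length is the shortest sequence's length; the default
    number of sweeps per restart is 100 * N. Fully deterministic given the
    seed.

    Instances whose full offset grid has at most ``exhaustive_limit``
    combinations are solved exactly by enumeration instead of sampling —
    single-site moves cannot escape some local optima on very small
    instances, and enumeration is cheap there.
    """
    if isinstance(seqs, CDR3Set):
        sequences = list(seqs.sequences)
    else:
        sequences = list(seqs)
    if not sequences:
        raise ValueError("no sequences to align")
    L = min(len(s) for s in sequences) if core_length is None else core_length
    for s in sequences:
        if len(s) < L:
            raise ValueError(f"sequence {s!r} shorter than core length {L}")
    n = len(sequences)
    sweeps = 100 * n if iterations is None else iterations
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)

    n_combos = 1.0
    for s in sequences:
        n_combos *= len(s) - L + 1
    if n_combos <= exhaustive_limit:
        offsets, _ = exhaustive_best_offsets(sequences, L, pseudocount, bg)
        cores = [s[o : o + L] for s, o in zip(sequences, offsets)]
        return offsets, build_pssm(cores, pseudocount, bg)

    # residue-index arrays for every (sequence, offset) core window
    max_off = [len(s) - L for s in sequences]
    idx = [
        np.array(
            [[AA_INDEX[a] for a in s[o : o + L]] for o in range(m + 1)], dtype=int
        )
        for s, m in zip(sequences, max_off)
    ]
    pos = np.arange(L)

    uniform = bool(np.allclose(bg, bg[0]))
    if uniform:
        # count-value lookup table: log-odds depends only on the count
        lut = np.log2(
            (np.arange(n + 1) + pseudocount * bg[0])
            / ((n - 1 + pseudocount) * bg[0])
        )

    best_offsets, best_score = None, -np.inf
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng([seed, restart])
        offsets = [int(rng.integers(0, m + 1)) for m in max_off]
        counts = np.zeros((L, 20), dtype=np.int64)
        for i in range(n):
            np.add.at(counts, (pos, idx[i][offsets[i]]), 1)

        def offset_scores(i: int) -> np.ndarray:
            # leave-one-out log-odds of every candidate window of sequence i
            if uniform:
                return lut[counts[pos, idx[i]]].sum(axis=1)
            logm = np.log2((counts + pseudocount * bg) / ((n - 1 + pseudocount) * bg))
            return logm[pos, idx[i]].sum(axis=1)

        temps = np.geomspace(t_start, t_end, num=max(sweeps, 2))
        for sweep in range(sweeps):
            t = temps[sweep]
            for i in rng.permutation(n):
                np.add.at(counts, (pos, idx[i][offsets[i]]), -1)
                logits = offset_scores(i) / t
                logits -= logits.max()
                cdf = np.cumsum(np.exp(logits))
                u = rng.random() * cdf[-1]
                offsets[i] = min(int(np.searchsorted(cdf, u, side="right")), max_off[i])
                np.add.at(counts, (pos, idx[i][offsets[i]]), 1)

        # greedy refinement: argmax moves until a full pass makes no change
        # (pass cap guards against cycling under non-uniform backgrounds)
        changed, passes = True, 0
        while changed and passes < 100:
            changed = False
            passes += 1
            for i in range(n):
                np.add.at(counts, (pos, idx[i][offsets[i]]), -1)
                scores = offset_scores(i)
                best = int(np.argmax(scores))
                if best != offsets[i] and scores[best] > scores[offsets[i]] + 1e-12:
                    offsets[i] = best
                    changed = True
                np.add.at(counts, (pos, idx[i][offsets[i]]), 1)

        total = total_alignment_score(sequences, offsets, L, pseudocount, bg)
        if total > best_score:
            best_offsets, best_score = list(offsets), total

    cores = [s[o : o + L] for s, o in zip(sequences, best_offsets)]
    return best_offsets, build_pssm(cores, pseudocount, bg)


def exhaustive_best_offsets(
    seqs: Sequence[str], core_length: int,
    pseudocount: float = 20.0, background: np.ndarray | None = None,
) -> tuple[list[int], float]:
    """Brute-force search over every offset combination (tiny instances only)."""
    ranges = [range(len(s) - core_length + 1) for s in seqs]
    best, best_score = None, -np.inf
    for combo in itertools.product(*ranges):
        sc = total_alignment_score(seqs, combo, core_length, pseudocount, background)
        if sc > best_score:
            best, best_score = list(combo), sc
    return best, best_score


def pbpc(pssm_pos: PSSM, pssm_neg: PSSM, alpha: float = 0.05) -> PBPCResult:
    """Position-wise Pearson correlation of two PSSMs' log-odds columns.

    Per position, r over the 20 amino-acid scores; two-sided p from the
    t(18) distribution. Positions with p >= alpha are flagged
    non-correlative; zero-variance (degenerate) columns get r = nan,
    p = 1 and are flagged.
    """
    if pssm_pos.core_length != pssm_neg.core_length:
        raise ValueError("PSSMs have different core lengths")
    L = pssm_pos.core_length
    r = np.full(L, np.nan)
    p = np.ones(L)
    degenerate = np.zeros(L, dtype=bool)
    for i in range(L):
        x, y = pssm_pos.matrix[i], pssm_neg.matrix[i]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            degenerate[i] = True
            continue
        res = stats.pearsonr(x, y)
        r[i], p[i] = res.statistic, res.pvalue
    flagged = p >= alpha
    return PBPCResult(r=r, p_value=p, flagged=flagged, alpha=alpha, degenerate=degenerate)


def pairwise_identity_similarity(
    seqs: Sequence[str],
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent identity and similarity matrices from global pairwise alignment.

    Identity = matches / alignment length * 100; similarity additionally
    counts substitutions with a positive score under the substitution
    matrix. Gap columns count toward the alignment length.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    matrix = substitution_matrices.load(substitution_matrix)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    n = len(seqs)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(seqs[i], seqs[j])[0]
            a, b = str(aln[0]), str(aln[1])
            matches = positives = 0
            for ca, cb in zip(a, b):
                if ca == "-" or cb == "-":
                    continue
                if ca == cb:
                    matches += 1
                    positives += 1
                elif matrix[ca, cb] > 0:
                    positives += 1
            length = len(a)
            ident[i, j] = ident[j, i] = 100.0 * matches / length
            simil[i, j] = simil[j, i] = 100.0 * positives / length
    return ident, simil


def glycine_conservation_report(
    seqs: Sequence[str], offsets: Sequence[int], core_length: int,
    result: PBPCResult | None = None,
):
    """Per-position residue composition of the aligned cores.

    Reports each residue's frequency, the glycine fraction, and (when a
    PBPC result is supplied) whether the position was flagged
    non-correlative — positions where motifs differ are frequently
    glycine-rich in CDR3 loops.
    """
    import pandas as pd

    cores = [s[o : o + core_length] for s, o in zip(seqs, offsets)]
    counts = np.zeros((core_length, 20))
    for c in cores:
        for p, a in enumerate(c):
            counts[p, AA_INDEX[a]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, columns=list(AA20))
    df.insert(0, "position", np.arange(1, core_length + 1))
    df["glycine_fraction"] = freqs[:, AA_INDEX["G"]]
    if result is not None:
        df["flagged"] = result.flagged
        df["p_value"] = result.p_value
    else:
        df["flagged"] = False
    return df


def pssm_to_tsv(pssm: PSSM, path) -> None:
    import pandas as pd

    pd.DataFrame(pssm.matrix, columns=list(AA20)).to_csv(path, sep="\t", index=False)


def pssm_to_json(pssm: PSSM) -> dict:
    return {
        "core_length": pssm.core_length,
        "pseudocount": pssm.pseudocount,
        "background": pssm.background.tolist(),
        "alphabet": AA20,
        "matrix": pssm.matrix.tolist(),
    }
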