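# Methods

This note documents the models, conventions, and numerical choices behind
`fusionpept`, and what the synthetic-data generators do and do not
emulate.

## Chimeric transcripts and ORFs

A fusion transcript is the exact concatenation of a 5'-parent and a
3'-parent nucleotide segment; the breakpoint offset equals the 5' segment
length, so coordinates below the breakpoint are 5'-parent derived.
Internally all coordinates are 0-based half-open; every human-facing
report is 1-based inclusive.

ORF enumeration is deliberately simple and fully specified, because an
"ORF count" is meaningless without its definition: ATG-initiated,
sense-strand only, three frames, extending to the first in-frame stop
(included in the nucleotide interval, excluded from the protein) or — by
default (`require_stop=False`) — to the 3' end. Within one (frame,
terminating-stop) group only the longest ATG-initiated ORF is reported.
The default `min_aa=25` suppresses spurious micro-ORFs. All of these
knobs are arguments, since published ORF censuses depend on them; the
enumerator is verified against an exhaustive position-scan oracle on
1,000 random sequences.

A codon split by the breakpoint is assigned to the 3' side:
`junction_protein_index` returns the number of *complete* codons lying
5' of the breakpoint, so `protein[:j]` is entirely 5'-parent encoded.
This affects per-residue origin labels only, never the sequence itself.

Codons containing `N` translate to `X`; start/stop recognition requires
exact bases. Translation delegates to Biopython's standard table.

In-silico PCR is exact-match only (the use case is verifying printed
primer pairs against a known template, where a single mismatch would be a
design error, and mismatch-tolerant models are out of scope). A forward
site is paired with the nearest downstream reverse-complement site whose
footprint does not overlap the forward footprint; the amplicon length
includes both primer footprints. Degenerate bases in primers are
rejected.

## Fusion-call consensus filter

Four stages in a fixed order: adjacent-normal background subtraction →
all-caller intersection → split-read requirement → actionable-gene
intersection. Design choices:

- Fusion identity is the ordered (gene5, gene3) symbol pair, compared
  case-insensitively. Callers disagree on exact breakpoint coordinates,
  so gene-level matching is the only identity that survives a
  multi-caller intersection.
- Background subtraction is cohort-wide: a fusion observed in any normal
  sample, by any caller, is removed from every tumor. Per-patient scoping
  would keep recurrent technical artifacts that happen to be absent from
  one patient's normal.
- Spanning reads never qualify a call on their own (`min_split=1`
  default); discordant-pair-only evidence is the dominant source of
  false-positive fusion calls.

Stage order matters for the per-stage counts but not for the final set
(all four predicates commute as filters); the shipped order is pinned by
a regression test.

## Binder thresholds and consensus

IC50 ≤ 500 nM and %Rank ≤ 10 define "strong" under the two predictor
dialects; both boundaries are inclusive (a peptide printed at exactly
500 nM is conventionally a strong binder) and configurable. When merged
runs produce multiple values for one (peptide, allele, metric), the best
(minimum) value wins. Consensus requires strength under both metrics.
HLA names are normalized to two-field `HLA-<locus>*<gg>:<pp>` before any
matching; extra fields are dropped because binder logic is two-field.

Wild-type controls are single-parent 9-mers whose nearest edge sits
exactly `gap` residues from the junction (default 2); alternative
readings of "two amino acids away" are reachable through `gap`.

## ELISpot positivity

Rates, not raw counts, are compared — replicate wells may differ in
plated cells — with rate_i = spots_i · 10⁶ / cells_i, summarized as mean
and SEM (sample SD / √n; 0 for n = 1). Positivity is the conjunction:
mean rate strictly greater than 20 spots/10⁶ cells AND ≥ 3-fold over the
same-donor non-stimulated control. A zero-control fold ratio is defined
by flooring the control mean at ε = 1 spot/10⁶ cells (configurable); with
a zero control the fold criterion reduces to mean rate ≥ 3ε.

## Clonotypes and module scores

A clonotype is keyed by the concatenated CDR3α and CDR3β amino-acid
sequences. Cells lacking either chain are excluded from clonotype
statistics but retained in composition breakdowns. "Expanded" means
carried by ≥ 2 cells within the grouping unit. Top clonotypes are ranked
by the proportion of each clonotype's cells that come from stimulated
samples (ties: cell count descending, then clonotype id — making the
ranking invariant to input row order); a condition-size-normalized
variant is available via `normalized=True` for unbalanced designs.

Module scores implement the standard binned-control scheme: genes are
ranked by mean expression and cut into `n_bins` (default 25) equal-count
bins; for each module gene, `n_control_per_gene` (default 50) control
genes are sampled with replacement (seeded) from its bin, excluding
module genes; the score is mean(module) − mean(control pool) per cell.
This cancels expression-magnitude artifacts, and a constant matrix scores
exactly zero. The implementation is cross-checked in the test suite
against scanpy's scorer on planted data.

## Gibbs core alignment

Single-cluster alignment of variable-length sequences to a fixed-length
core: each sequence gets one offset; a sweep resamples every sequence's
offset from the Boltzmann distribution over its windows, scored by the
leave-one-out log-odds sum against the other sequences' cores, with the
temperature annealing geometrically from 1.5 to 0.05 over 100·N sweeps;
a final greedy pass applies argmax moves until a pass changes nothing.
The chain restarts 5 times from seeded initializations and the best
total leave-one-out score wins. Everything is deterministic given the
seed. Multi-cluster deconvolution and trash-bin outlier handling are
deliberately omitted: the use case clusters each chain's set as a single
group, and correctness is validated by planted-motif recovery rather
than output-identity with any external clustering tool.

Instances whose full offset grid has ≤ 5,000 combinations are solved by
exact enumeration instead: single-site moves provably cannot escape some
local optima on very small instances (e.g. three identical cores form a
basin from which the globally better paired configuration is unreachable
by any one-sequence move), and enumeration is cheap there. The default
core length is the length of the shortest sequence in the set being
aligned, mirroring the "core size = smallest positive sequence" rule;
the comparison pipeline applies the positive set's core length to both
sets.

## PSSMs and the pseudocount

`M[p][a] = log2((c_{p,a} + pc·bg_a) / ((N + pc)·bg_a))` with uniform
background (bg_a = 0.05) and additive pseudocount `pc` default **20**,
i.e. one pseudo-observation per residue. The choice matters: with a
small pseudocount (pc·bg ≪ 1) the log-odds of zero-count cells are
dominated by sampling noise — for N = 30, a cell moves from −4.95 to
−0.56 on the strength of a single observation — and that noise dilutes
the Pearson correlation between two PSSMs' columns, masking genuinely
shared structure. Laplace-level smoothing stabilizes the columns while
leaving the informative high-count cells essentially unchanged.
BLOSUM-weighted pseudocounts are out of scope; the uniform-background
version keeps the estimator transparent and exactly reproducible.

## Position-based Pearson correlation (PBPC)

At each core position the two 20-long log-odds columns (positive =
expanded clonotypes, negative = naive-only clonotypes) are Pearson-
correlated; significance uses t = r·√((n−2)/(1−r²)) with n = 20 amino
acids (df = 18), two-sided. Positions with p ≥ α (default 0.05) are
flagged *non-correlative* — the positions where the two motifs differ.
Two caveats are intrinsic to this test and documented rather than hidden:

- It is two-sided, so a strongly anti-correlated position (the two sets
  prefer different residues so systematically that the columns mirror)
  is *significant* and not flagged, even though the motifs disagree
  there. Flagged positions are those with no detectable linear
  relationship.
- A truly divergent position behaves null-like, so it is flagged with
  probability ≈ 0.95, never 1; with k divergent positions the chance of
  flagging all of them is ≈ 0.95^k. Any claim of complete recovery is
  only meaningful for small k.

Degenerate (zero-variance) columns get r = NaN, p = 1, and are flagged
with a "degenerate" annotation. Log-odds columns are the correlated
quantity; frequency-space correlation is available by building the PSSM
and exponentiating.

Percent identity/similarity between CDR3s uses Biopython's global
pairwise aligner with BLOSUM62 (gap open −10, extend −0.5 by default);
identity = matches / alignment length, similarity additionally counts
substitutions with positive BLOSUM score; gap columns count toward the
length.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (seed, parameters); each draws
from its own RNG stream derived from the master seed plus a stable
per-generator label, so adding a generator never perturbs another. Truth
records are JSON-serializable and sufficient to score the downstream
stage.

- **Fusion pair**: random parent segments around a planted ORF
  (default 150 aa, junction after residue 70, ~90-nt UTRs) built from
  one representative codon per residue, with an in-frame stop guarding
  the planted ATG; optional primers planted in the UTRs give an amplicon
  of known length spanning the junction. Not emulated: splice structure,
  codon-usage bias, repeated sequence.
- **Predictor tables**: IC50 log-uniform on [1, 50000] nM, %Rank uniform
  on (0, 100]; planted consensus pairs forced under both thresholds,
  every other pair forced over at least one. Real predictor score
  correlations between alleles are not modeled.
- **ELISpot**: spot counts Poisson(rate · cells/10⁶) with a baseline of
  5 spots/10⁶ cells, 3 replicates, 2×10⁵ cells/well; planted effects add
  to the rate. Plate effects and overdispersion are not modeled — with
  them, the false-positive rate of the dual rule would be higher than
  the near-zero rate measured here.
- **Repertoire**: 2 donors, 4,000 cells, 500 background clonotypes with
  power-law (exponent 1.2) frequencies present in both conditions
  (cytokine-media-driven expansion), naive cells drawing near-unique
  receptors. The 15 planted clonotypes model antigen-specific responses:
  present only in stimulated samples (for boost > 1), frequency boosted
  30-fold, cells preferentially active/exhausted. `expansion_boost=1`
  is the inert null used for calibration.
- **CDR3 sets** (30 + 30 sequences, 9-mer core, 0–4 residue flanks):
  both sets share a two-residue base preference (0.4/0.3) at
  non-divergent positions — the conserved loop chemistry that makes
  those positions correlate; at the planted divergent positions
  (default: one tryptophan position and one glycine position at 90%)
  the negative set is uniform, emulating a naive repertoire with no
  preference where antigen-driven clones converge. Real V(D)J
  recombination statistics and germline-templated flanks are not
  modeled, so passing tests demonstrate estimator behavior, not
  immunological realism.
- **Caller tables**: planted true fusions (tumor-only, all callers,
  split-read support) plus three background classes: shared-with-normal,
  partial-caller, and spanning-only. Truth lists the expected survivors
  given each fusion's actual caller coverage.

## Problem sizes

The shipped test and acceptance runs use: 1,000 random sequences for the
ORF oracle, 10,000 simulated column pairs for the PBPC null rate, 1,000
Poisson replicates for the ELISpot false-positive rate, 5 repertoires of
4,000 cells for clonotype recovery, and 10 planted CDR3 set pairs for
divergence recovery — sizes chosen so each check resolves its question
at single-CPU desk scale.

## Known limitations

- The ORF-census and amplicon calibrations against the published fusion
  sequence require that sequence file, which is not redistributed here;
  the corresponding checks run only when it is placed under
  `tests/data/`.
- The Gibbs aligner is single-cluster; sets mixing several unrelated
  motifs will be forced into one core.
- PBPC inherits the n = 20 two-sided Pearson test's resolution limits
  described above; with many truly divergent positions, complete
  recovery is statistically impossible by construction.
- The cross-reactivity module consumes an upstream screen's hit table;
  it never computes similarity or expression itself.
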