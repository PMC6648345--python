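# Methods

## Model

A chromatin state annotation assigns one of Q discrete states to each
fixed-width genomic bin (200 bp by default, matching ChromHMM). The unit of
analysis is the run-length *compressed* sequence: maximal runs of one state
collapse to a single symbol, with run sizes kept in bins. Compression is
essential — the quiescent state covers most of the genome in very long
stretches, and aligning uncompressed sequences lets shared quiescent length,
not shared state *patterns*, dominate the score.

Alignment is a Smith–Waterman-style dynamic program over compressed
sequences. With per-state weights W (equal weights by default), a match
scores +(W(k,S₁)+W(l,S₂)), a mismatch −ε_N·(W(k,S₁)+W(l,S₂)), and a
deletion −ε_D·W of the deleted state. Defaults ε_N = 1.5, ε_D = 1:
equivalent to a substitution matrix with +1 diagonal and −1.5 off-diagonal
(per unit weight) and a linear gap cost analogous to a gap-extend penalty
of 1. Larger penalties make the optimal alignment shorter and more local.

### Scoring modes

The recursion is floored at zero; three read-outs are exposed:

- `endpoint` (default): the value at the final cell M[n₁,n₂]. This is an
  *end-anchored* local score — equivalently, the best score over all
  suffix pairs of S₁ and S₂ aligned in full. It rewards sequences whose
  (arbitrarily long) tails share structure.
- `max`: the matrix maximum — classic Smith–Waterman. Preferred when the
  shared pattern may sit anywhere inside large windows (the tiling
  workflows and the motif-clustering example use it for that reason).
- `global`: the unfloored recursion with zero boundary rows (leading gaps
  free); the score may be negative.

The formulation defines the headline score at the final cell while calling
the method local; both the final-cell and matrix-maximum read-outs are
therefore implemented and documented rather than silently merged. An
end-anchored score can legitimately be 0 (every candidate alignment is
negative), so downstream consumers that require strictly positive pairwise
scores (the similarity matrix below) work best in `max` mode, where any
shared state yields a positive score.

Traceback ties are broken deterministically: diagonal match > diagonal
mismatch > deletion in S₁ (up) > deletion in S₂ (left) > zero reset,
favoring contiguous diagonals. Only the single best alignment is reported.
The DP kernel is compiled with numba (plain-Python fallback); full
tracebacks refuse matrices beyond ~4·10⁸ cells and a two-row score-only
path (`align_score`) covers arbitrarily long sequences in O(min n) memory.

### Weights

Equal weights (all 1) are the default. Frequency-based weights are
w(s) = −log f(s), rescaled so the frequency-weighted mean Σ f(s)·w(s) = 1:
positive, decreasing in frequency, and on the same scale as equal weights.
The rescaling constant is this package's choice; state frequencies can be
counted per compressed occurrence (default, the scale the aligner sees) or
per raw bin.

## Normalization against permutation nulls

Raw scores of different queries are not comparable (they scale with length
and composition). The null model permutes a sequence's (state, run)
segments uniformly and re-merges adjacent equal states: composition and
run-length distribution are preserved exactly, only sequential order is
destroyed. `normalized_score` reports z = (raw − null mean)/max(null sd, τ)
over B = 100 permutations of the target (τ = 1e-8, with a degenerate-null
flag when the null collapses).

In the horizontal scan the statistic is a *best hit over m−1 targets*, so
the null must be a best hit too: each null replicate permutes every other
region and records the query's best score against that randomized database.
Normalizing the winner against permutations of the single best target
would leave the max-selection bias in place (pure-noise tracks would
average z ≈ +2.5 at m = 20 instead of ≈ 0). With the database null, a
track with no recurrent structure centers at z ≈ 0 and a randomized
epigenome scores near 0 by construction. This costs O(m²B) alignments per
scan, which the compiled kernel absorbs.

## Workflows

- **Horizontal scan**: tile the genome into 500 kb windows (trailing
  partial windows kept iff ≥ half a window — small unstable tails are
  dropped), extract each window's compressed sequence, align all pairs,
  and report each region's best hit (ties by genome order) with its
  normalized score. Empty windows are skipped and reported.
- **Vertical alignment**: raw pairwise scores of one region across
  epigenomes. Group contrasts use the two-sample one-sided Wilcoxon
  rank-sum test (H₁: within-group scores stochastically larger); the exact
  null is enumerated when the combined sample is ≤ 20 and tie-free,
  otherwise the normal approximation with tie correction is used
  (scipy.stats.mannwhitneyu provides both branches; the exact branch is
  verified against full enumeration in the tests). P-values are reported
  unadjusted — regions are *ranked* by p — with Benjamini–Hochberg left to
  the caller. Self-pairs are excluded from within-group lists.
- **Naïve baseline**: M_naïve = −Σ_q (p₁q − p₂q)², proportions over
  compressed occurrences by default (consistent with the aligner's input);
  always in [−2, 0].
- **Region similarity**: Aᵢⱼ = score(i,j)/(α·max_{k≠r} score(k,r)) with
  α = 1.1 and unit diagonal; D = 1 − A feeds average-linkage clustering
  (cluster count user-set, default 4, or chosen at the largest merge gap).
  Raw scores enter A — the scaling *is* the normalization here.
- **Epigenome clustering**: each epigenome is represented by its vector of
  horizontal scores; pairwise Pearson correlations define the 1 − r
  distance, clustered with average linkage (regions missing anywhere are
  dropped listwise; zero-variance vectors are an error).

## Synthetic data

The generator draws, per chromosome, successive (state, run) pairs: the
state from a stationary distribution conditioned on differing from the
previous state, the run geometric with a per-state mean. Defaults: Q = 15,
quiescent (state 15) stationary mass 0.6 with mean dwell 50 bins, all
other states mean dwell 3 bins — long quiescent stretches over a busy
foreground. Motifs (short state successions such as the tandem 'eg'
repeat, states 5/7 = weak transcription / enhancer) are planted by
overwriting the background at random offsets inside chosen 500 kb tiles,
so chromosome lengths are unchanged and each planted tile's compressed
sequence contains the motif verbatim. Cohorts share background parameters
and plant one motif per group at a common region. Everything is a pure
function of (config, seed).

Two emergent properties matter for interpretation. First, conditioning
each draw on differing from the previous state with a dominant quiescent
state produces quasi-periodic returns to quiescence — a genuine sequential
structure that segment permutation destroys. Simulated "real" tracks
therefore out-score their randomized controls genome-wide, not just at
planted motifs, mirroring how real epigenomes behave. Second, what the
generator does *not* emulate: position-specific state grammar (promoter →
gene-body ordering), inter-chromosomal heterogeneity, assembly gaps, and
annotation noise. Passing simulation tests shows the machinery detects
planted sequential structure at realistic composition — not that effect
sizes transfer to real data.

## Study sizes used in the checks

The simulation studies run at desk scale by design: the
real/randomized/hybrid study uses one 10 Mb chromosome (20 tiles of
500 kb), a 5-tandem-repeat 'eg' motif planted 3× in 10 of the 20 tiles
(5 even- and 5 odd-indexed, so both hybrid phases retain motif tiles),
B = 100 null replicates, 20 simulation seeds; the cohort study uses 2
groups × 3 tracks on a 2 Mb chromosome with group motifs at one tile; the
null-calibration check uses 200 i.i.d. query/target pairs of 40 segments
each. The acceptance script runs the same analyses at 5 (scan) / 10
(cohort) replicates with B = 50.

## Known limitations

- Linear (per-state) deletion costs only; no affine gaps and no
  state-pair-specific substitution matrix.
- Single optimal alignment; co-optimal paths are not enumerated.
- Empirical permutation nulls only; no analytic (Karlin–Altschul-style)
  significance theory for this score.
- The end-anchored default score and the matrix-maximum score can differ
  substantially on long windows; users should pick the mode that matches
  their question (end-similarity vs anywhere-similarity).
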