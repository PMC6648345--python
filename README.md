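# epialign

Local alignment of chromatin state sequences.

Genome segmentation tools such as ChromHMM compress multi-track epigenomic
signals (histone marks, DNA methylation) into a single sequence of discrete
chromatin states — one label per 200 bp bin, e.g. the 15-state Roadmap model
with states like TssA (active promoter), Enh (enhancer), Tx (transcription)
and Quies (quiescent). `epialign` quantifies the similarity of two such
annotations by *aligning* them, so that recurrent successions of states
(promoter → transcription → enhancer …) can be found and compared the way
sequence aligners compare DNA. It is aimed at regulatory genomicists who
want to ask: which regions of an epigenome share non-random chromatin state
patterns, and how does the same region's chromatin state sequence differ
across tissues, sexes or species?

## The algorithm

Raw per-bin state sequences are first run-length compressed (`abbcc → abc`),
because single states — above all the quiescent state — cover long
uninterrupted stretches whose lengths would otherwise dominate the
alignment. The compressed sequences S₁, S₂ (lengths n₁, n₂) are aligned by
a modified Smith–Waterman dynamic program. An alignment is a status string
F over {m, n, d₁, d₂} (match, mismatch, deletion in S₁/S₂) with index
vectors U₁, U₂, scored as H = Σᵢ h(fᵢ, u₁ᵢ, u₂ᵢ) with per-state weights W:

    match:     +( W(k,S₁) + W(l,S₂) )
    mismatch:  −ε_N · ( W(k,S₁) + W(l,S₂) )     ε_N = 1.5 by default
    deletion:  −ε_D · W(k,S)                     ε_D = 1   by default

The DP matrix M is filled with a zero floor (local alignment); the default
score is the value at the final cell M[n₁,n₂] (an end-anchored local score),
with the classic matrix-maximum Smith–Waterman score (`mode="max"`) and an
unfloored global variant (`mode="global"`) also available. Weights are
equal (all 1) by default, or frequency-based (w(s) = −log f(s), rescaled)
to up-weight rare states.

Around the core aligner:

- **Normalization** — scores of different queries are not comparable, so a
  score is standardized (z-score) against alignments to segment-permuted
  targets: composition and run-length distribution preserved, sequential
  order destroyed.
- **Horizontal scan** — tile an epigenome into 500 kb regions, align every
  region against every other, and report each region's normalized
  best-hit-except-self score. High scores flag regions sharing non-random
  recurrent patterns.
- **Vertical alignment** — align the same region across epigenomes and
  contrast within-group vs between-group scores with a one-sided Wilcoxon
  rank-sum test (e.g. brain-vs-brain against brain-vs-heart).
- **Baseline** — the naïve proportion score M_naïve = −‖P₁−P₂‖², which
  ignores order, for head-to-head comparison.
- **Clustering** — pairwise region similarities Aᵢⱼ = score(i,j) / (1.1 ·
  max score), D = 1 − A, average linkage; and epigenome-level clustering of
  horizontal-score vectors with the (1 − Pearson r) distance.
- **Simulation** — synthetic segmentations with geometric dwell times, a
  dominant quiescent state and planted recurrent motifs, plus randomized
  and alternating real/randomized hybrid controls.

## Worked example

```python
from epialign import StateAlphabet, align, format_alignment, from_letters

alpha = StateAlphabet.from_size(4)
s1 = from_letters("abca", alpha)
s2 = from_letters("aba", alpha)
print(format_alignment(align(s1, s2), s1, s2, alphabet=alpha))
```

prints

```
score=5 mode=endpoint eps_n=1.5 eps_d=1 weights=equal
E1 E2 E3 E1
 |  |  -  |
E1 E2  - E1
```

The optimal alignment matches states 1, 2 and 4 of `abca` to `aba` and
deletes the third (`c`): 2 + 2 − 1 + 2 = 5. The status string is
F = m,m,d₁,m with U₁ = [1,2,3,4] and U₂ = [1,2,0,3].

Longer narrative examples live in `examples/` (pairwise alignment,
horizontal scan, vertical cohort comparison, motif clustering), and the
`epialign` command exposes the same workflows from the shell
(`epialign align abca aba`, `epialign scan segmentation.bed --seed 1`, …).

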