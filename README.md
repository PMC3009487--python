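# irredclass

Alignment-free comparison and classification of protein (or generic)
sequences by **irredundant common patterns**.

Most string kernels for remote homology detection count overlapping,
mutually dependent patterns, so the contribution of a conserved region is
counted many times over. `irredclass` restricts attention to the
*irredundant* common patterns of a sequence pair — the smallest set of
patterns from which every common pattern, together with its occurrence
list, can be reconstructed. Each pattern has solid first and last
characters and may contain don't cares (`.`) matching any residue; there
are at most *m + n − 1* irredundant common patterns for sequences of
lengths *m* and *n*, and each is the meet (trimmed position-wise
consensus) of one sequence with a suffix of the other.

A pair is scored by

&nbsp;&nbsp;&nbsp;&nbsp;Score(s₁, s₂) = Σ<sub>p ∈ 𝓘(s₁,s₂)</sub> ln ( F_p / E[F_p] )

where F_p = q₁ + q₂ is the number of occurrences of pattern *p* in the
two sequences and E[F_p] = ((m − |p| + 1) + (n − |p| + 1)) · P(p) its
expectation under an i.i.d. background, with P(p) the product of the
background probabilities of the solid characters (BLOSUM62 marginal
amino-acid frequencies by default; don't cares contribute a factor 1).
The N×N score matrix over a sequence collection is used as a precomputed
(generally indefinite) kernel for a soft-margin SVM; per-family rankings
are evaluated with ROC, ROC50 and the median rate of false positives
(mRFP). Projecting the trained weights α back through the patterns gives
a per-position *footprint* over a test sequence whose peaks suggest
candidate functional regions.

## Worked example

The alternating pair `abababab` / `babababa` has twelve maximal common
patterns but only two irredundant ones:

```sh
$ printf '>s1\nabababab\n>s2\nbabababa\n' > toy.fasta
$ irredclass extract --fasta toy.fasta --id1 s1 --id2 s2 --alphabet-mode generic
pattern	positions_1	positions_2	q1	q2
abababa	1	2	1	1
bababab	2	1	1	1
```

`abababa` occurs at position 1 of the first sequence and position 2 of
the second, once in each (q₁ = q₂ = 1); every other common pattern
(`ababa`, `abab`, `ab`, …) is deducible from these two and is filtered
out. Scoring the pair over a uniform two-letter background:

```python
>>> from irredclass import BackgroundModel, Sequence, pair_score
>>> bg = BackgroundModel.uniform("ab")
>>> pair_score(Sequence("s1", "abababab"), Sequence("s2", "babababa"), bg)
8.317766166719343
```

Each 7-mer occurs twice in total (F = 2) against an expectation of
4 · 2⁻⁷ windows-times-probability, so the score is
2 · ln(2 / (4 · 2⁻⁷)) = 2 · ln 64 ≈ 8.3178: both shared patterns are far
more frequent than chance, and the pair scores highly.

The full pipeline on real data: `irredclass score-matrix` to build the
kernel, `irredclass classify` to train on a family split and report
ROC / ROC50 / mRFP, and `irredclass footprint` to write the per-position
discriminative weight of a test sequence. `irredclass fixtures`
generates i.i.d. synthetic sequences with an optional planted motif for
experimentation. See `irredclass --help`.

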