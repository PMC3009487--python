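# Methods

## Pattern model

A sequence is a string over an alphabet Σ (the 20 standard amino acids by
default; any alphabet in generic mode). A *pattern* is a string over
Σ ∪ {`.`} whose first and last characters are solid and whose length is
at least two; the don't care `.` matches any single residue. We read the
shape constraint as "solid ends, length ≥ 2", which admits length-2
all-solid patterns. Occurrence positions are 1-based and anchored at the
pattern's first (always solid) character.

A *common pattern* of a pair (s₁, s₂) occurs in both sequences and
carries its maximal location list. Pattern p₁ is a *subpattern* of p₂
(p₁ ≼ p₂) when it matches inside p₂ at some offset, don't cares of p₁
matching anything; an occurrence of p₁ is *covered* by p₂ when it lies in
p₂'s location list shifted by such an offset. A common pattern is
*maximal* when no other common pattern implies it with an identical
shift-adjusted location list, and a maximal pattern is *irredundant* when
its occurrences cannot all be covered by other maximal patterns. The
irredundant set is the smallest basis from which every common pattern and
its locations can be reconstructed without the sequences; for an
identical pair it is exactly the sequence itself. Its size is bounded by
m + n − 1.

## Extraction algorithm

Every irredundant common pattern is the meet — position-wise consensus
with flanking don't cares trimmed — of one sequence with a suffix of the
other. The extractor therefore:

1. computes the m + n − 1 suffix meets (the offset-0 alignment once),
   discarding meets shorter than 2;
2. merges alignments that produce the same meet string, accumulating the
   *exposed occurrences* — the two positions each alignment reveals — in
   per-sequence counters I₁, I₂ (nonzero only at exposed positions);
3. counts the full occurrence lists q₁, q₂ of each meet by a naive
   wildcard scan, and keeps a meet iff some position satisfies
   I₁[j] = q₂ or I₂[j] = q₁.

The merge in step 2 is essential: the counter test needs every witness,
and the same meet string can arise from several alignments. Counters can
never exceed the occurrence count of the opposite sequence; this is
asserted defensively. Output is sorted by (first occurrence in s₁,
pattern string) for reproducible serialization. The overall cost is the
naive O((m+n)³) of the wildcard searches, which is adequate for the
sequence lengths the pipeline targets; no FFT matching is used.

A definition-level brute-force oracle backs the extractor in the test
suite: candidates are the meets of all cross suffix pairs closed under
the meet operation at every relative offset (iterated pairwise meets
realize the meet of any window subset, so the closure contains every
composition-maximal pattern), filtered by location-list dominance for
maximality, and by the coverage definition for redundancy. It is
exponential in the worst case and guarded by an input-size cap
(m + n ≤ 40); the suite checks set-and-location equality between
extractor and oracle on hundreds of random pairs over alphabets of size
2–4 with m + n ≤ 30.

## Scoring

Each irredundant pattern contributes ln(F_p / E[F_p]) with F_p = q₁ + q₂
and

    E[F_p] = ((m − |p| + 1) + (n − |p| + 1)) · P(p),

the standard i.i.d. occurrence expectation: window count times match
probability, where P(p) multiplies the background probabilities of the
solid characters and gives don't cares probability 1. The pair score is
the unweighted sum over the irredundant set (empty set → 0). Negative
contributions are kept: the statistic is a log-likelihood ratio and
truncation would bias the sum. Both the per-pattern form and the plain
sum are design choices of this package — length-normalized or
length-weighted variants would be drop-in replacements behind
`expected_count` and `pair_score` — made because the per-pattern
log-ratio is also the weight the footprint uses, which fixes the
functional form up to the aggregation.

The default background is the BLOSUM62 marginal amino-acid frequency
table (embedded as constants, renormalized to sum to 1; the frequencies,
not a substitution-derived quantity, since the expectation model is
i.i.d.). Non-standard residues admitted by the permissive alphabet mode
receive a configurable floor probability (default 0.005, no
renormalization). The identical-pair diagonal of the score matrix
follows the extraction rule — one pattern, the sequence itself, F = 2 —
rather than a special value.

## Kernel and classifier

The score matrix is symmetric but generally indefinite. The default
(`raw`) hands it to the SVM as-is and relies on the optimizer's
iteration cap; `shift` adds λI with λ = max(0, −λ_min) + ε (ε = 1e−9) to
make it positive semidefinite (within 1e−8 in the tests), and
`normalize` applies cosine normalization after the shift. The classifier
is an interface contract — fit on a precomputed kernel with an iteration
cap, expose per-training-sequence weights α, labels and bias, score by
the kernel expansion Σ αᵢyᵢK(t,i) + b — filled by scikit-learn's libsvm
backend (C = 1.0 and cap 10⁶ by default, both exposed in the run
configuration; no claim is made that these match any particular
historical run).

## Evaluation metrics

- **ROC**: normalized area under true positives vs false positives over
  all thresholds; ties receive half credit (trapezoidal).
- **ROC50**: the same area truncated at 50 false positives and
  normalized by #positives · min(50, #negatives), so it stays in [0, 1]
  on small experiments and equals ROC when there are ≤ 50 negatives.
  Truncation clips curve segments at the 50th false positive; a vertical
  jump exactly at the boundary contributes nothing, a diagonal tie
  segment is linearly interpolated.
- **mRFP**: the fraction of negatives scoring at or above the median
  positive score (an even positive count uses the interpolated median).
  This is the definition standard in the remote-homology literature and
  is unit-locked by the tests.

## Footprint

For a test sequence and trained weights α over the training set, each
pattern p extracted from (s_test, sᵢ) carries weight ln(F_p/E[F_p])·αᵢ.
The weight is added, for *every* occurrence of p in the test sequence,
at each position under a solid character; coverage is positional, so
per-occurrence accumulation is the consistent choice. Don't-care
positions are untouched, weights (including negative ones from
negative-class support vectors or under-represented patterns) accumulate
as-is, and an option restricts to positive-weight training sequences.
The footprint is linear in α and additive over disjoint training sets;
positions never covered by a solid character are exactly 0. Peak
reporting is deliberately simple — the argmax plus a top-quantile
threshold (default: the 90th percentile of nonzero weights) — since the
histograms are meant for visual inspection.

## Synthetic data

The fixture generator draws residues i.i.d. from a configurable
background (uniform over the chosen alphabet, or explicit frequencies) —
the same generative model the scoring expectation assumes — and can
plant a motif (a pattern string, don't cares left as the random draw) at
fixed or random positions. Default batches are 10 sequences of length
40–60, a scale at which pairwise extraction is instantaneous and planted
motifs of length ≥ 6 are recovered reliably over the 20-letter alphabet.
A fixed seed fully determines the output. What this emulates — and what
it does not: real protein families share many partially overlapping,
unevenly conserved segments with compositional bias, not a single
exactly-placed motif over an i.i.d. background, so passing tests
demonstrate correctness of the machinery, not classification performance
on real families. Benchmark-scale evaluation (thousands of sequences,
dozens of families) requires external curated datasets and is outside
the test suite.

## Numerical and degenerate-input choices

- Meets with fewer than two surviving characters are an explicit empty
  marker (`None`), never a zero-length pattern.
- A pattern longer than both sequences has no occurrence window; scoring
  it is an error rather than a zero expectation.
- Sequences are validated once (strict 20-letter alphabet by default;
  permissive mode keeps B/Z/X/U/O as solid symbols; generic mode accepts
  arbitrary non-wildcard symbols without case folding, for toy
  alphabets).
- Score-matrix and footprint writers serialize floats with `repr`, so
  file round-trips are bit-exact.
- The problem sizes in the test suite (pairs with m + n ≤ 30 against the
  brute-force oracle, 200 random pairs, 6–12 sequence score matrices)
  were chosen so the full suite runs in a few seconds while still
  exercising alphabets of size 2–4, where pattern collisions — and hence
  redundancy — are most frequent.

## Known limitations

- Pairwise only: no multi-sequence (> 2) irredundant pattern discovery.
- Exact matching only: no mismatch tolerance or character classes.
- The i.i.d. background ignores local composition and repeats; scores
  are not calibrated p-values.
- The raw kernel's indefiniteness is handled pragmatically (iteration
  cap or eigenvalue shift), not by a principled indefinite-kernel
  learner.
- Footprints are per-test-sequence; no cross-sequence aggregation over a
  multiple alignment is provided.
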