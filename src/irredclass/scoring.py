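"""Pairwise scoring of sequences by their irredundant common patterns.

Each irredundant common pattern ``p`` of a pair ``(s1, s2)`` contributes
``ln(F_p / E[F_p])``: the log-ratio of its observed occurrence count
``F_p = q1 + q2`` to its expectation under an i.i.d. background,

    E[F_p] = ((m - |p| + 1) + (n - |p| + 1)) * P(p),

where ``P(p)`` is the product of the background probabilities of the
pattern's solid characters (a don't care has probability 1).  The pair
score is the plain sum of the contributions over the irredundant set; an
empty set scores 0.  Scores over a sequence collection form a symmetric
matrix used as a (generally indefinite) kernel for a maximum-margin
classifier; :func:`kernel_prepare` offers an eigenvalue shift and cosine
normalization for optimizers that require positive semidefiniteness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .extraction import IrredundantSet, extract_irredundant
from .pattern import DONT_CARE, Pattern, Sequence

__all__ = [
    "BLOSUM62_BACKGROUND",
    "BackgroundModel",
    "PatternScore",
    "ScoreMatrix",
    "pattern_probability",
    "expected_count",
    "score_patterns",
    "pair_score",
    "score_matrix",
    "kernel_prepare",
]

logger = logging.getLogger(__name__)

# BLOSUM62 background (marginal) amino-acid frequencies, from the Henikoff
# block counts as distributed with BLAST; renormalized at model
# construction so they sum to 1 exactly.
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.07422, "R": 0.05161, "N": 0.04465, "D": 0.05363, "C": 0.02469,
    "Q": 0.03426, "E": 0.05431, "G": 0.07415, "H": 0.02621, "I": 0.06792,
    "L": 0.09891, "K": 0.05816, "M": 0.02499, "F": 0.04742, "P": 0.03854,
    "S": 0.05723, "T": 0.05089, "W": 0.01303, "Y": 0.03228, "V": 0.07292,
}

#: Default probability assigned to non-standard solid symbols kept by the
#: permissive alphabet mode (no renormalization is applied for these).
EXTRA_SYMBOL_FLOOR = 0.005


@dataclass(frozen=True)
class BackgroundModel:
    """An i.i.d. residue background: symbol -> probability in (0, 1].

    The don't-care character always has probability exactly 1, so it never
    needs an entry.  ``floor`` is returned for solid symbols absent from
    the table when it is set; otherwise a missing symbol is an error.
    """

    probabilities: dict[str, float]
    source: str = "custom"
    floor: float | None = None

    def probability(self, symbol: str) -> float:
        if symbol == DONT_CARE:
            return 1.0
        try:
            return self.probabilities[symbol]
        except KeyError:
            if self.floor is not None:
                return self.floor
            raise KeyError(
                f"no background probability for symbol {symbol!r} "
                f"(source {self.source})"
            ) from None

    @classmethod
    def blosum62(cls, *, floor: float | None = EXTRA_SYMBOL_FLOOR) -> "BackgroundModel":
        """The BLOSUM62 marginal amino-acid frequencies (renormalized)."""
        total = sum(BLOSUM62_BACKGROUND.values())
        probs = {aa: p / total for aa, p in BLOSUM62_BACKGROUND.items()}
        return cls(probabilities=probs, source="blosum62", floor=floor)

    @classmethod
    def uniform(cls, symbols: str) -> "BackgroundModel":
        """Uniform background over the given symbols (toy alphabets)."""
        syms = sorted(set(symbols))
        if not syms:
            raise ValueError("uniform background needs at least one symbol")
        p = 1.0 / len(syms)
        return cls(probabilities={s: p for s in syms}, source="uniform")


@dataclass(frozen=True)
class PatternScore:
    """Observed vs expected occurrence counts of one pattern."""

    pattern: Pattern
    observed: int            # F_p = q1 + q2, >= 2 for any common pattern
    expected: float          # E[F_p] > 0
    contribution: float      # ln(observed / expected)


def pattern_probability(p: Pattern | str, bg: BackgroundModel) -> float:
    """Product of the background probabilities of the pattern's symbols.

    Don't cares contribute a factor of 1.
    """
    symbols = p.symbols if isinstance(p, Pattern) else p
    prob = 1.0
    for c in symbols:
        prob *= bg.probability(c)
    return prob


def expected_count(
    p: Pattern | str, m: int, n: int, bg: BackgroundModel
) -> float:
    """Expected occurrences of ``p`` across two i.i.d. sequences.

    Window count ``(m - |p| + 1) + (n - |p| + 1)`` (each clamped at zero)
    times the pattern probability.  A pattern longer than both sequences
    has no window and cannot be scored.
    """
    length = len(p.symbols if isinstance(p, Pattern) else p)
    windows = max(m - length + 1, 0) + max(n - length + 1, 0)
    if windows == 0:
        raise ValueError(
            f"pattern of length {length} exceeds both sequence lengths "
            f"({m}, {n}); expected count is zero"
        )
    return windows * pattern_probability(p, bg)


def score_patterns(
    irr: IrredundantSet, m: int, n: int, bg: BackgroundModel
) -> list[PatternScore]:
    """Per-pattern scores for an extracted irredundant set."""
    scores = []
    for cp in irr:
        f_p = cp.q1 + cp.q2
        e_p = expected_count(cp.pattern, m, n, bg)
        scores.append(
            PatternScore(
                pattern=cp.pattern,
                observed=f_p,
                expected=e_p,
                contribution=math.log(f_p / e_p),
            )
        )
    return scores


def pair_score(
    s1: Sequence, s2: Sequence, bg: BackgroundModel
) -> float:
    """Score(s1, s2) = sum of ln(F_p / E[F_p]) over the irredundant set.

    Negative contributions (observed below expectation) are kept; a pair
    with no common pattern scores 0.  Symmetric in its arguments.
    """
    irr = extract_irredundant(s1, s2)
    scores = score_patterns(irr, len(s1), len(s2), bg)
    return float(sum(ps.contribution for ps in scores))


@dataclass(frozen=True)
class ScoreMatrix:
    """A symmetric matrix of pairwise scores over named sequences."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match the id list")
        if not np.allclose(v, v.T):
            raise ValueError("score matrix must be symmetric")

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def submatrix(
        self, row_ids: list[str], col_ids: list[str]
    ) -> np.ndarray:
        rows = [self.index(i) for i in row_ids]
        cols = [self.index(i) for i in col_ids]
        return self.values[np.ix_(rows, cols)]


def score_matrix(
    seqs: list[Sequence],
    bg: BackgroundModel,
    *,
    log_every: int = 100,
) -> ScoreMatrix:
    """Pairwise score matrix over a sequence set (diagonal included).

    Each unordered pair is extracted and scored once; the matrix is
    symmetric by construction.  The diagonal follows the identical-pair
    extraction rule (the single irredundant pattern is the sequence
    itself), not a special value.
    """
    ids = tuple(s.id for s in seqs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in score_matrix input")
    n = len(seqs)
    values = np.zeros((n, n))
    done = 0
    total = n * (n + 1) // 2
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = pair_score(seqs[i], seqs[j], bg)
            done += 1
            if log_every and done % log_every == 0:
                logger.info("score_matrix: %d/%d pairs scored", done, total)
    return ScoreMatrix(ids=ids, values=values)


def kernel_prepare(
    M: ScoreMatrix, mode: str = "raw", *, eps: float = 1e-9
) -> ScoreMatrix:
    """Prepare a score matrix for use as a precomputed SVM kernel.

    ``raw``
        Pass-through: the indefinite matrix is handed to the optimizer
        as-is (the iteration-cap contract lives on the classifier side).
    ``shift``
        Add ``lambda * I`` with ``lambda = max(0, -min_eigenvalue) + eps``,
        making the matrix positive semidefinite.
    ``normalize``
        Cosine normalization ``K_ij / sqrt(K_ii * K_jj)`` applied after the
        shift, so every diagonal entry is 1.
    """
    if mode == "raw":
        return M
    if mode not in ("shift", "normalize"):
        raise ValueError(f"unknown kernel mode {mode!r}")
    values = M.values.astype(float)
    smallest = float(np.linalg.eigvalsh(values)[0])
    lam = max(0.0, -smallest) + eps
    values = values + lam * np.eye(len(M.ids))
    if mode == "normalize":
        d = np.sqrt(np.diag(values))
        values = values / np.outer(d, d)
    return ScoreMatrix(ids=M.ids, values=values)
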