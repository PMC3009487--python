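"""Discriminative-pattern footprints along a test sequence.

A trained classifier assigns a weight ``alpha_i`` to each training
sequence.  For a test sequence, every pair (test, training-i) yields a
set of irredundant common patterns; each pattern ``p`` carries the weight
``ln(F_p / E[F_p]) * alpha_i``.  That weight is added, for every
occurrence of ``p`` in the test sequence, to each position lying under a
*solid* character of the pattern (don't-care positions are untouched).
Summing over all patterns and all training sequences gives a per-position
histogram whose peaks suggest conserved, candidate functional regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .extraction import extract_irredundant
from .pattern import Sequence, find_occurrences
from .scoring import BackgroundModel, PatternScore, expected_count

__all__ = [
    "Footprint",
    "pattern_weight",
    "accumulate_footprint",
    "footprint_peaks",
    "export_footprint",
    "load_footprint",
]


@dataclass(frozen=True)
class Footprint:
    """Per-position accumulated pattern weight for one test sequence."""

    test_id: str
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.weights)


def pattern_weight(ps: PatternScore, alpha_i: float) -> float:
    """Weight of one pattern from one training sequence: ln(F/E) * alpha."""
    return ps.contribution * alpha_i


def accumulate_footprint(
    s_test: Sequence,
    training: list[tuple[Sequence, float]],
    bg: BackgroundModel,
    *,
    positive_only: bool = False,
) -> Footprint:
    """Accumulate the weighted solid-character coverage along ``s_test``.

    For every training sequence with weight ``alpha``, every irredundant
    common pattern of the pair, and every occurrence of that pattern in
    the test sequence, the pattern's weight is added at each position
    under a solid character.  Weights are accumulated as-is, including
    negative ones; ``positive_only`` restricts to training sequences with
    ``alpha > 0`` (positive-class support vectors).
    """
    weights = np.zeros(len(s_test))
    for s_i, alpha in training:
        if alpha == 0.0 or (positive_only and alpha <= 0.0):
            continue
        irr = extract_irredundant(s_test, s_i)
        m, n = len(s_test), len(s_i)
        for cp in irr:
            f_p = cp.q1 + cp.q2
            e_p = expected_count(cp.pattern, m, n, bg)
            w = math.log(f_p / e_p) * alpha
            solid = cp.pattern.solid_offsets
            # s_test is the first sequence of the pair by construction.
            for pos in cp.positions(1):
                for off in solid:
                    weights[pos - 1 + off] += w
    return Footprint(test_id=s_test.id, weights=weights)


def footprint_peaks(
    fp: Footprint, *, quantile: float = 0.9
) -> tuple[int, tuple[int, ...]]:
    """Simple peak report: argmax position and the top-quantile positions.

    Returns the 1-based position of the maximum weight and the 1-based
    positions whose weight reaches the ``quantile`` level of the nonzero
    weights.  With an all-zero footprint both parts are empty-ish: the
    argmax is position 1 and the peak list is empty.
    """
    nonzero = fp.weights[fp.weights != 0]
    argmax = int(np.argmax(fp.weights)) + 1
    if len(nonzero) == 0:
        return argmax, ()
    level = float(np.quantile(nonzero, quantile))
    peaks = tuple(int(i) + 1 for i in np.nonzero(fp.weights >= level)[0])
    return argmax, peaks


def export_footprint(
    fp: Footprint,
    seq: Sequence,
    path,
    *,
    fmt: str = "tsv",
    header_comments: tuple[str, ...] = (),
) -> None:
    """Write a footprint as per-position rows (1-based, contiguous).

    ``tsv`` rows are ``id, position, residue, weight``; the
    ``bedgraph-like`` variant writes ``id, start, end, weight`` with
    start = end = the position.  Weights use ``repr`` so a reload is
    bit-exact.
    """
    if fmt not in ("tsv", "bedgraph-like"):
        raise ValueError(f"unknown footprint format {fmt!r}")
    if len(fp) != len(seq):
        raise ValueError("footprint length does not match the sequence")
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        if fmt == "tsv":
            fh.write("id\tposition\tresidue\tweight\n")
            for k, w in enumerate(fp.weights):
                fh.write(
                    f"{fp.test_id}\t{k + 1}\t{seq.residues[k]}\t{float(w)!r}\n"
                )
        else:
            for k, w in enumerate(fp.weights):
                fh.write(f"{fp.test_id}\t{k + 1}\t{k + 1}\t{float(w)!r}\n")


def load_footprint(path) -> Footprint:
    """Reload a TSV footprint written by :func:`export_footprint`."""
    test_id = ""
    weights: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("id\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            test_id = parts[0]
            weights.append(float(parts[-1]))
    return Footprint(test_id=test_id, weights=np.array(weights))
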