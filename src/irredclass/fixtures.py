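"""Synthetic sequence generation for tests and demonstrations.

Sequences are drawn i.i.d. from a configurable residue background — the
same generative model the scoring expectation assumes — with an optional
*planted motif*: a pattern string (don't cares allowed) written over the
random residues at a fixed or random position in every sequence, so that
pairs of generated sequences provably share a common pattern.  A fixed
seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pattern import DONT_CARE, Sequence

__all__ = ["FixtureSpec", "generate_fixtures"]

#: Alphabetically ordered 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic sequence batch.

    ``background`` maps symbols to probabilities (uniform over
    ``alphabet`` when omitted); ``plant_positions`` gives a 1-based motif
    start per sequence, or ``None`` for a random placement per sequence.
    """

    count: int = 10
    length_range: tuple[int, int] = (40, 60)
    alphabet: str = AMINO_ACIDS
    background: dict[str, float] | None = None
    motif: str | None = None
    plant_positions: tuple[int, ...] | None = None
    seed: int = 0
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length range")
        if self.motif is not None and len(self.motif) > lo:
            raise ValueError("planted motif longer than the minimum length")
        if self.plant_positions is not None and len(self.plant_positions) != self.count:
            raise ValueError("need one plant position per sequence")


def generate_fixtures(spec: FixtureSpec) -> list[Sequence]:
    """Draw ``spec.count`` i.i.d. sequences, optionally planting a motif.

    Don't-care positions of the motif are left as the i.i.d. draw, so only
    the motif's solid characters are written.  Identical specs produce
    identical output.
    """
    rng = np.random.default_rng(spec.seed)
    symbols = list(spec.alphabet)
    if spec.background is None:
        probs = np.full(len(symbols), 1.0 / len(symbols))
    else:
        probs = np.array([spec.background[s] for s in symbols], dtype=float)
        probs = probs / probs.sum()
    lo, hi = spec.length_range
    seqs: list[Sequence] = []
    for k in range(spec.count):
        length = int(rng.integers(lo, hi + 1))
        chars = list(rng.choice(symbols, size=length, p=probs))
        if spec.motif is not None:
            if spec.plant_positions is not None:
                pos = spec.plant_positions[k]
                if not 1 <= pos <= length - len(spec.motif) + 1:
                    raise ValueError(
                        f"plant position {pos} out of range for length {length}"
                    )
            else:
                pos = int(rng.integers(1, length - len(spec.motif) + 2))
            for off, c in enumerate(spec.motif):
                if c != DONT_CARE:
                    chars[pos - 1 + off] = c
        seqs.append(Sequence(id=f"{spec.id_prefix}{k:03d}", residues="".join(chars)))
    return seqs
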