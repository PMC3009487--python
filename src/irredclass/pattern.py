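"""Pattern algebra over sequences with don't-care wildcards.

A *pattern* is a string over an alphabet extended with the wildcard
(don't-care) character ``.``, whose first and last characters are solid
(concrete residues) and whose length is at least two.  A don't care
matches any single residue.  The module provides the basic operations on
patterns and sequences used by the extraction algorithm:

- :func:`consensus` / :func:`meet` — position-wise agreement of two
  strings, with don't cares at mismatches; the meet trims the flanking
  don't cares so the result is a well-formed pattern.
- :func:`is_subpattern` — the partial order ``p1 <= p2`` ("p2 implies
  p1"): p1 occurs inside p2 at some offset, with don't cares of p1
  matching anything.
- :func:`find_occurrences` — naive wildcard string search.
- :func:`covers` — whether an occurrence of one pattern is accounted for
  by the shifted location list of a pattern that implies it.

All positions in the public API are 1-based and refer to the position of
the pattern's first (solid) character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

DONT_CARE = "."

#: The 20 standard amino acids.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard residue codes tolerated in permissive mode.
AMBIGUOUS_RESIDUES = frozenset("BZXUO")


class AlphabetError(ValueError):
    """A residue fell outside the configured alphabet in strict mode."""


@dataclass(frozen=True)
class Sequence:
    """A validated sequence with an identifier.

    Attributes
    ----------
    id : str
        Record identifier (FASTA description line up to first whitespace).
    residues : str
        The residue string; every character is a solid symbol.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a Sequence must contain at least one residue")
        if DONT_CARE in self.residues:
            raise ValueError("sequences may not contain don't-care characters")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class Pattern:
    """A pattern: solid first and last character, length >= 2.

    ``symbols`` is a plain string over the alphabet plus ``.``; the shape
    invariants are enforced at construction time, so any ``Pattern``
    instance is well formed.
    """

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols
        if len(s) < 2:
            raise ValueError(f"pattern too short: {s!r}")
        if s[0] == DONT_CARE or s[-1] == DONT_CARE:
            raise ValueError(f"pattern ends must be solid: {s!r}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @property
    def solid_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the solid characters within the pattern."""
        return tuple(k for k, c in enumerate(self.symbols) if c != DONT_CARE)


class Occurrence(NamedTuple):
    """An occurrence of a pattern: which sequence (1 or 2) and where.

    ``pos`` is the 1-based position of the pattern's first character.
    """

    seq_ref: int
    pos: int


#: A maximal set of occurrences of a pattern across a sequence pair.
LocationList = tuple[Occurrence, ...]

StrOrSeq = Union[str, Sequence, Pattern]


def _chars(s: StrOrSeq) -> str:
    if isinstance(s, Sequence):
        return s.residues
    if isinstance(s, Pattern):
        return s.symbols
    return s


def validate_sequence(
    raw: str,
    *,
    id: str = "seq",
    alphabet: Iterable[str] | None = PROTEIN_ALPHABET,
    case_fold: bool = True,
    strict: bool = True,
) -> Sequence:
    """Validate raw text into a :class:`Sequence`.

    Parameters
    ----------
    raw
        Residue text; internal whitespace is stripped.
    alphabet
        Allowed residue symbols, or ``None`` to accept any non-wildcard
        character (useful for toy sequences over small alphabets).
    case_fold
        Upper-case the input before validation.  Disable for raw mode,
        e.g. lower-case toy alphabets.
    strict
        With the protein alphabet, reject ambiguity codes (B, Z, X, U, O);
        when off they are kept as ordinary solid symbols.

    Raises
    ------
    ValueError
        Empty input.
    AlphabetError
        A residue outside the alphabet in strict mode.
    """
    text = "".join(raw.split())
    if not text:
        raise ValueError("empty sequence")
    if case_fold:
        text = text.upper()
    if alphabet is not None:
        allowed = set(alphabet)
        if not strict:
            allowed |= AMBIGUOUS_RESIDUES
        bad = sorted(set(text) - allowed)
        if bad:
            raise AlphabetError(
                f"sequence {id!r} contains residues outside the alphabet: "
                + "".join(bad)
            )
    elif DONT_CARE in text:
        raise AlphabetError(f"sequence {id!r} contains the wildcard character")
    return Sequence(id=id, residues=text)


def consensus(s1: StrOrSeq, s2: StrOrSeq) -> str:
    """Position-wise consensus of two strings.

    Position ``i`` of the result is ``s1[i]`` where the inputs agree and a
    don't care where they differ; the result has the length of the shorter
    input.  May be empty of solid characters (or empty altogether).
    """
    a, b = _chars(s1), _chars(s2)
    return "".join(x if x == y else DONT_CARE for x, y in zip(a, b))


def meet(s1: StrOrSeq, s2: StrOrSeq) -> Pattern | None:
    """Meet of two strings: the consensus with flanking don't cares trimmed.

    Returns ``None`` (the explicit empty marker) when fewer than two
    characters survive trimming, i.e. no well-formed pattern exists.
    """
    trimmed = consensus(s1, s2).strip(DONT_CARE)
    if len(trimmed) < 2:
        return None
    return Pattern(trimmed)


def _char_le(a: str, b: str) -> bool:
    return a == DONT_CARE or a == b


def is_subpattern(p1: StrOrSeq, p2: StrOrSeq) -> frozenset[int]:
    """All offsets at which ``p1`` occurs inside ``p2``.

    ``d`` is in the result iff ``|p1| <= |p2|`` and every character of
    ``p1`` is either a don't care or equal to the aligned character of
    ``p2``.  An empty set means ``p1`` is not a subpattern of ``p2``.
    Note the order matters: a solid character of ``p1`` does not match a
    don't care of ``p2``.
    """
    a, b = _chars(p1), _chars(p2)
    if len(a) > len(b):
        return frozenset()
    return frozenset(
        d
        for d in range(len(b) - len(a) + 1)
        if all(_char_le(a[j], b[j + d]) for j in range(len(a)))
    )


def find_occurrences(p: StrOrSeq, s: StrOrSeq) -> tuple[int, ...]:
    """1-based positions at which pattern ``p`` occurs in ``s``.

    Naive scan; a don't care matches any residue.
    """
    pat, seq = _chars(p), _chars(s)
    hits = []
    for j in range(len(seq) - len(pat) + 1):
        if all(_char_le(c, seq[j + k]) for k, c in enumerate(pat)):
            hits.append(j + 1)
    return tuple(hits)


def covers(
    p1: StrOrSeq,
    locations1: Iterable[Occurrence],
    p2: StrOrSeq,
    occ: Occurrence,
) -> bool:
    """Is the occurrence ``occ`` of ``p2`` covered by ``p1``?

    True iff ``p2`` is a subpattern of ``p1`` at some offset ``i`` and
    ``occ`` lies in the location list of ``p1`` shifted right by ``i``
    (within the same sequence).
    """
    locs = {(o.seq_ref, o.pos) for o in locations1}
    return any(
        (occ.seq_ref, occ.pos - i) in locs for i in is_subpattern(p2, p1)
    )
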