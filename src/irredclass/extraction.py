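"""Extraction of irredundant common patterns from a sequence pair.

Every irredundant common pattern of two sequences is the meet of one
sequence with a suffix of the other, so there are at most ``m + n - 1`` of
them.  The extractor enumerates those meets, records for each meet the
*exposed occurrences* (the pair of positions revealed by the suffix
alignment that produced it) in per-sequence counters ``I1``/``I2``, counts
the full occurrence lists ``q1``/``q2`` by wildcard search, and keeps a
meet iff some exposed occurrence has a counter equal to the occurrence
count in the *other* sequence — the counter characterization of
irredundancy.

The module also carries a brute-force oracle (:func:`oracle_maximal_patterns`,
:func:`oracle_is_redundant`) that realizes the definitions directly:
maximal common patterns are obtained by closing all cross suffix-pair
meets under the meet operation and filtering by location-list dominance,
and a pattern is redundant when all of its occurrences are covered by
other maximal patterns.  The oracle is exponential-ish and guarded by an
input-size cap; it exists to validate the extractor, not to replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pattern import (
    DONT_CARE,
    LocationList,
    Occurrence,
    Pattern,
    Sequence,
    consensus,
    covers,
    find_occurrences,
    is_subpattern,
)

__all__ = [
    "MeetRecord",
    "CommonPattern",
    "IrredundantSet",
    "enumerate_suffix_meets",
    "irredundancy_filter",
    "extract_irredundant",
    "oracle_maximal_patterns",
    "oracle_is_redundant",
]


@dataclass
class MeetRecord:
    """A distinct suffix-alignment meet with its exposed-occurrence counters.

    ``counters1``/``counters2`` are 1-based integer arrays (index 0 unused)
    over the positions of the first/second sequence; they are nonzero only
    at exposed occurrence positions, and accumulate across the alignments
    that produced the same meet string.
    """

    pattern: Pattern
    exposed: set[Occurrence] = field(default_factory=set)
    counters1: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    counters2: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


@dataclass(frozen=True)
class CommonPattern:
    """A common pattern with its maximal location list.

    ``q1``/``q2`` are the occurrence counts in the first/second sequence;
    a common pattern has ``q1 >= 1`` and ``q2 >= 1``.
    """

    pattern: Pattern
    locations: LocationList
    q1: int
    q2: int

    def positions(self, seq_ref: int) -> tuple[int, ...]:
        return tuple(o.pos for o in self.locations if o.seq_ref == seq_ref)


@dataclass(frozen=True)
class IrredundantSet:
    """The irredundant common patterns of a sequence pair."""

    pair: tuple[str, str]
    patterns: tuple[CommonPattern, ...]

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def pattern_strings(self) -> tuple[str, ...]:
        return tuple(str(cp.pattern) for cp in self.patterns)


def _aligned_meet(
    a: str, off1: int, b: str, off2: int
) -> tuple[Pattern, int, int] | None:
    """Meet of ``a[off1:]`` with ``b[off2:]`` plus the exposed positions.

    Returns ``(pattern, pos1, pos2)`` with 1-based positions of the
    pattern's first character in each full sequence, or ``None`` when the
    meet is empty.
    """
    cons = consensus(a[off1:], b[off2:])
    stripped = cons.strip(DONT_CARE)
    if len(stripped) < 2:
        return None
    lead = len(cons) - len(cons.lstrip(DONT_CARE))
    return Pattern(stripped), off1 + lead + 1, off2 + lead + 1


def enumerate_suffix_meets(s1: Sequence, s2: Sequence) -> list[MeetRecord]:
    """All distinct meets of one sequence with a suffix of the other.

    Processes the ``m + n - 1`` suffix alignments (the full-pair alignment
    once); alignments producing the same meet string are merged into one
    :class:`MeetRecord`, with exposed occurrences and counters accumulated
    across alignments.  Meets shorter than two characters are discarded.
    """
    a, b = s1.residues, s2.residues
    m, n = len(a), len(b)
    records: dict[str, MeetRecord] = {}
    alignments = [(0, k) for k in range(n)] + [(j, 0) for j in range(1, m)]
    for off1, off2 in alignments:
        hit = _aligned_meet(a, off1, b, off2)
        if hit is None:
            continue
        pat, j1, j2 = hit
        rec = records.get(pat.symbols)
        if rec is None:
            rec = MeetRecord(
                pattern=pat,
                counters1=np.zeros(m + 1, dtype=int),
                counters2=np.zeros(n + 1, dtype=int),
            )
            records[pat.symbols] = rec
        rec.exposed.add(Occurrence(1, j1))
        rec.exposed.add(Occurrence(2, j2))
        rec.counters1[j1] += 1
        rec.counters2[j2] += 1
    return list(records.values())


def irredundancy_filter(
    records: list[MeetRecord], s1: Sequence, s2: Sequence
) -> IrredundantSet:
    """Keep the meets whose counters witness irredundancy.

    A meet ``p`` is irredundant iff it has an exposed occurrence ``j`` in
    one sequence whose counter equals the number of occurrences of ``p``
    in the other sequence: ``I1[j] = q2`` or ``I2[j] = q1``.
    """
    kept: list[CommonPattern] = []
    for rec in records:
        occ1 = find_occurrences(rec.pattern, s1)
        occ2 = find_occurrences(rec.pattern, s2)
        q1, q2 = len(occ1), len(occ2)
        # An exposed occurrence in s1 is witnessed by a distinct suffix of
        # s2 per increment, so counters can never exceed the occurrence
        # count of the other sequence on well-formed inputs.
        if rec.counters1.max(initial=0) > q2 or rec.counters2.max(initial=0) > q1:
            raise RuntimeError(
                f"exposed-occurrence counters exceed occurrence counts for "
                f"pattern {rec.pattern.symbols!r}"
            )
        if np.any(rec.counters1 == q2) or np.any(rec.counters2 == q1):
            locations = tuple(
                [Occurrence(1, j) for j in occ1] + [Occurrence(2, j) for j in occ2]
            )
            kept.append(
                CommonPattern(pattern=rec.pattern, locations=locations, q1=q1, q2=q2)
            )
    kept.sort(key=lambda cp: (cp.positions(1)[0], cp.pattern.symbols))
    result = IrredundantSet(pair=(s1.id, s2.id), patterns=tuple(kept))
    assert len(result) <= len(s1) + len(s2) - 1
    return result


def extract_irredundant(s1: Sequence | str, s2: Sequence | str) -> IrredundantSet:
    """Extract all irredundant common patterns of a sequence pair.

    Deterministic; the result is sorted by (first occurrence position in
    the first sequence, pattern string) and holds at most ``m + n - 1``
    patterns.  An empty set is returned when the sequences share no common
    pattern of length >= 2.
    """
    if isinstance(s1, str):
        s1 = Sequence("s1", s1)
    if isinstance(s2, str):
        s2 = Sequence("s2", s2)
    return irredundancy_filter(enumerate_suffix_meets(s1, s2), s1, s2)


# ---------------------------------------------------------------------------
# Brute-force oracle (test-scale machinery)
# ---------------------------------------------------------------------------


def _pattern_meets(p: str, q: str) -> set[str]:
    """All well-formed meets of ``p`` with ``q`` over every relative offset."""
    out: set[str] = set()
    for x, y in ((p, q), (q, p)):
        for off in range(len(x)):
            trimmed = consensus(x[off:], y).strip(DONT_CARE)
            if len(trimmed) >= 2:
                out.add(trimmed)
    return out


def oracle_maximal_patterns(
    s1: Sequence | str, s2: Sequence | str, *, max_total: int = 40
) -> tuple[CommonPattern, ...]:
    """Brute-force enumeration of all maximal common patterns.

    Seeds the candidate set with the meets of every suffix of one sequence
    against every suffix of the other, closes it under the meet operation
    (all relative offsets) to fixpoint, attaches full maximal location
    lists, and finally discards any pattern implied by another common
    pattern with an identical shift-adjusted location list (dominance in
    composition or length).

    Guarded by ``max_total`` on ``m + n``: this is test-only machinery.
    """
    a = s1.residues if isinstance(s1, Sequence) else s1
    b = s2.residues if isinstance(s2, Sequence) else s2
    m, n = len(a), len(b)
    if m + n > max_total:
        raise ValueError(f"oracle size guard exceeded: m+n={m + n} > {max_total}")

    cand: set[str] = set()
    for i in range(m):
        for j in range(n):
            trimmed = consensus(a[i:], b[j:]).strip(DONT_CARE)
            if len(trimmed) >= 2:
                cand.add(trimmed)
    # Close under meets to fixpoint: the meet of two common patterns is
    # itself common, and iterated pairwise meets realize the meet of any
    # window subset.
    frontier = list(cand)
    while frontier:
        p = frontier.pop()
        for q in list(cand):
            for new in _pattern_meets(p, q):
                if new not in cand:
                    cand.add(new)
                    frontier.append(new)

    commons: list[CommonPattern] = []
    for pat_str in sorted(cand):
        occ1 = find_occurrences(pat_str, a)
        occ2 = find_occurrences(pat_str, b)
        if occ1 and occ2:
            locations = tuple(
                [Occurrence(1, j) for j in occ1] + [Occurrence(2, j) for j in occ2]
            )
            commons.append(
                CommonPattern(
                    pattern=Pattern(pat_str),
                    locations=locations,
                    q1=len(occ1),
                    q2=len(occ2),
                )
            )

    maximal: list[CommonPattern] = []
    for p in commons:
        p_locs = set(p.locations)
        dominated = False
        for q in commons:
            if q.pattern == p.pattern or len(q.locations) != len(p.locations):
                continue
            for d in is_subpattern(p.pattern, q.pattern):
                if {(o.seq_ref, o.pos + d) for o in q.locations} == {
                    (o.seq_ref, o.pos) for o in p_locs
                }:
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            maximal.append(p)
    return tuple(maximal)


def oracle_is_redundant(
    p: CommonPattern, maximals: tuple[CommonPattern, ...]
) -> bool:
    """Definition-level redundancy test.

    True iff every occurrence of ``p`` (in both sequences) is covered by an
    occurrence of some maximal common pattern other than ``p``.
    """
    others = [q for q in maximals if q.pattern != p.pattern]
    return all(
        any(covers(q.pattern, q.locations, p.pattern, occ) for q in others)
        for occ in p.locations
    )
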