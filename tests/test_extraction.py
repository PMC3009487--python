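"""Irredundant-pattern extraction: worked examples, counter semantics,
and equivalence with the definition-level brute-force oracle."""

import numpy as np
import pytest

from irredclass import (
    Occurrence,
    Sequence,
    enumerate_suffix_meets,
    extract_irredundant,
    find_occurrences,
    irredundancy_filter,
    oracle_is_redundant,
    oracle_maximal_patterns,
)

from conftest import random_sequence


def _meet_by_pattern(s1, s2):
    return {str(r.pattern): r for r in enumerate_suffix_meets(s1, s2)}


class TestSuffixMeets:
    def test_counter_walkthrough(self, counter_pair):
        """The suffix alignment at position 3 of the second sequence yields
        the meet a.a.a, exposing one occurrence per sequence."""
        s1, s2 = counter_pair
        rec = _meet_by_pattern(s1, s2)["a.a.a"]
        assert rec.counters1[2] == 1 and rec.counters1.sum() == 1
        assert rec.counters2[4] == 1 and rec.counters2.sum() == 1
        assert rec.exposed == {Occurrence(1, 2), Occurrence(2, 4)}

    def test_identical_short_pair(self):
        s = Sequence("x", "ab")
        recs = _meet_by_pattern(s, Sequence("y", "ab"))
        assert set(recs) == {"ab"}
        assert recs["ab"].exposed == {Occurrence(1, 1), Occurrence(2, 1)}

    def test_distinct_meets_of_alternating_pair(self, toy_pair):
        recs = _meet_by_pattern(*toy_pair)
        assert set(recs) == {"abababa", "ababa", "aba", "bababab", "babab", "bab"}

    def test_counters_accumulate_over_alignments(self):
        # for (abab, abab), the meet "ab" arises from the two shifted
        # alignments; its counters accumulate across them
        s = Sequence("x", "abab")
        rec = _meet_by_pattern(s, Sequence("y", "abab"))["ab"]
        assert rec.counters1.tolist() == [0, 1, 0, 1, 0]
        assert rec.counters2.tolist() == [0, 1, 0, 1, 0]


class TestIrredundancyFilter:
    def test_rejects_the_redundant_meet(self, counter_pair):
        """a.a.a has I1[2]=1 < q2=2 and I2[4]=1 < q1=2, hence redundant."""
        s1, s2 = counter_pair
        irr = irredundancy_filter(enumerate_suffix_meets(s1, s2), s1, s2)
        assert "a.a.a" not in irr.pattern_strings()

    def test_alternating_pair_enumeration(self, toy_pair):
        s1, s2 = toy_pair
        irr = extract_irredundant(s1, s2)
        by_pattern = {str(cp.pattern): cp for cp in irr}
        assert set(by_pattern) == {"abababa", "bababab"}
        assert by_pattern["abababa"].locations == (
            Occurrence(1, 1),
            Occurrence(2, 2),
        )
        assert by_pattern["bababab"].locations == (
            Occurrence(1, 2),
            Occurrence(2, 1),
        )

    @pytest.mark.parametrize(
        "residues", ["abab", "dadgggdistketvdedgsgtidfee", "xyzzy"]
    )
    def test_identical_pair_rule(self, residues):
        s = Sequence("s", residues)
        irr = extract_irredundant(s, Sequence("t", residues))
        assert irr.pattern_strings() == (residues,)

    def test_disjoint_alphabets(self):
        assert len(extract_irredundant("aaaa", "cccc")) == 0

    def test_identical_pair_rule_random(self):
        """For any sequence, (s, s) yields exactly one irredundant pattern:
        the sequence itself."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            s = random_sequence(rng, int(rng.integers(2, 20)), "abc")
            irr = extract_irredundant(s, Sequence("copy", s.residues))
            assert irr.pattern_strings() == (s.residues,)


class TestOracle:
    def test_twelve_maximal_patterns(self, toy_pair):
        maxi = oracle_maximal_patterns(*toy_pair)
        expected = {
            "abababa", "bababab", "ababab", "bababa", "ababa", "babab",
            "abab", "baba", "aba", "bab", "ab", "ba",
        }
        assert {str(m.pattern) for m in maxi} == expected

    def test_redundancy_calls_from_enumeration(self, toy_pair):
        maxi = oracle_maximal_patterns(*toy_pair)
        by_pattern = {str(m.pattern): m for m in maxi}
        assert oracle_is_redundant(by_pattern["ababa"], maxi)   # deduced from p1
        assert oracle_is_redundant(by_pattern["abab"], maxi)    # union of p1, p2
        assert not oracle_is_redundant(by_pattern["abababa"], maxi)
        assert not oracle_is_redundant(by_pattern["bababab"], maxi)

    def test_identical_pair_bruteforce(self):
        s = Sequence("s", "abab")
        maxi = oracle_maximal_patterns(s, Sequence("t", "abab"))
        irr = [m for m in maxi if not oracle_is_redundant(m, maxi)]
        assert [str(m.pattern) for m in irr] == ["abab"]

    def test_disjoint_pair_empty(self):
        assert oracle_maximal_patterns("ab", "cd") == ()

    def test_size_guard(self):
        with pytest.raises(ValueError):
            oracle_maximal_patterns("a" * 30, "b" * 30, max_total=40)


@pytest.fixture(scope="module")
def random_pairs():
    rng = np.random.default_rng(2024)
    pairs = []
    for _ in range(60):
        k = int(rng.integers(2, 5))
        alphabet = "abcd"[:k]
        m = int(rng.integers(2, 16))
        n = int(rng.integers(2, min(16, 31 - m)))
        pairs.append(
            (
                random_sequence(rng, m, alphabet),
                random_sequence(rng, n, alphabet),
            )
        )
    return pairs


class TestExtractionProperties:
    def test_oracle_equivalence(self, random_pairs):
        """Extractor output equals the maximal set minus the redundant
        patterns, including location lists."""
        for s1, s2 in random_pairs:
            maxi = oracle_maximal_patterns(s1, s2)
            oracle = {
                (str(p.pattern), p.locations)
                for p in maxi
                if not oracle_is_redundant(p, maxi)
            }
            mine = {
                (str(cp.pattern), cp.locations)
                for cp in extract_irredundant(s1, s2)
            }
            assert mine == oracle, (s1.residues, s2.residues)

    def test_linear_bound(self, random_pairs):
        for s1, s2 in random_pairs:
            assert len(extract_irredundant(s1, s2)) <= len(s1) + len(s2) - 1

    def test_suffix_meet_witness(self, random_pairs):
        """Every irredundant pattern is literally one of the suffix meets."""
        for s1, s2 in random_pairs:
            meets = set(_meet_by_pattern(s1, s2))
            assert set(extract_irredundant(s1, s2).pattern_strings()) <= meets

    def test_symmetry(self, random_pairs):
        for s1, s2 in random_pairs:
            fwd = {
                (str(cp.pattern), frozenset(cp.locations))
                for cp in extract_irredundant(s1, s2)
            }
            rev = {
                (
                    str(cp.pattern),
                    frozenset(Occurrence(3 - o.seq_ref, o.pos) for o in cp.locations),
                )
                for cp in extract_irredundant(s2, s1)
            }
            assert fwd == rev

    def test_location_list_maximality(self, random_pairs):
        for s1, s2 in random_pairs:
            for cp in extract_irredundant(s1, s2):
                assert cp.positions(1) == find_occurrences(cp.pattern, s1)
                assert cp.positions(2) == find_occurrences(cp.pattern, s2)
                assert cp.q1 >= 1 and cp.q2 >= 1
                assert cp.q1 + cp.q2 == len(cp.locations)
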