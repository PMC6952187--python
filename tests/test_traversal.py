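"""Candidate-assembly enumeration."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from plasmidplan.config import DesignConfig
from plasmidplan.model import Match
from plasmidplan.traversal import (
    all_synthetic_candidate,
    estimate_synth_count,
    select_seeds,
    traverse,
)


def _mk(qs, qe, entry="e", repo="db"):
    return Match(repo, entry, qs, qe, 0, qe - qs, "+", 100.0)


class TestSelectSeeds:
    def test_threshold_is_one_target_length(self):
        L = 1000
        matches = [_mk(s, s + 10, entry=f"e{s}")
                   for s in (0, 400, 999, 1000, 1500)]
        assert [m.query_start for m in select_seeds(matches, L)] == [0, 400, 999]

    def test_no_seed_when_all_start_beyond_L(self):
        assert select_seeds([_mk(1200, 1300)], 1000) == []

    def test_empty(self):
        assert select_seeds([], 1000) == []


class TestEstimateSynthCount:
    def test_gap_at_primer_fill_limit_costs_nothing(self, config):
        assert estimate_synth_count(20, config) == 0

    def test_zero_gap(self, config):
        assert estimate_synth_count(0, config) == 0

    def test_ceiling_division_for_large_gaps(self):
        from plasmidplan.config import CostCurve, CostTier, money
        cfg = DesignConfig(synthetic_fragment_curve=CostCurve(
            (CostTier(1000, money(100), False),)))
        assert estimate_synth_count(1600, cfg) == 2
        assert estimate_synth_count(1000, cfg) == 1
        assert estimate_synth_count(21, cfg) == 1


def _brute_force_chains(matches, L, config):
    """Reference enumerator: every ascending chain that closes the circle
    within the fragment budget, as a set of chain signatures."""
    import math
    found = set()
    ordered = sorted(matches, key=lambda m: m.query_start)
    for r in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, r):
            starts = [m.query_start for m in combo]
            ends = [m.query_end for m in combo]
            if starts[0] >= L or starts != sorted(set(starts)):
                continue
            if ends != sorted(set(ends)):
                continue        # a chain never anneals into an engulfed end
            close_at = starts[0] + L
            if any(m.query_start >= close_at for m in combo):
                continue
            count = len(combo)
            ok = True
            prev = None
            for m in combo:
                if prev is not None:
                    gap = m.query_start - prev
                    if gap > config.max_primer_fill_gap:
                        count += math.ceil(gap / config.max_synthetic_length)
                prev = m.query_end
            closing = close_at - combo[-1].query_end
            if closing > config.max_primer_fill_gap:
                count += math.ceil(closing / config.max_synthetic_length)
            if count > config.max_fragment_count:
                continue
            sig = frozenset((m.repo, m.entry, m.query_start % L) for m in combo)
            found.add(sig)
    return found


class TestTraverse:
    def test_single_full_length_match_gives_one_fragment_candidate(self, config):
        m = _mk(0, 1000, entry="whole")
        cands = traverse([m], 1000, config)
        assert len(cands) == 1
        assert cands[0].fragment_count == 1 and not cands[0].synth_spans

    def test_two_overlapping_matches_close_without_gaps(self, config):
        a, b = _mk(0, 600, entry="a"), _mk(550, 1050, entry="b")
        cands = traverse([a, b], 1000, config)
        two = [c for c in cands if len(c.matches) == 2]
        assert len(two) == 1
        assert two[0].synth_spans == []
        assert two[0].fragment_count == 2

    def test_partial_coverage_estimates_synthetic_fragments(self):
        from plasmidplan.config import CostCurve, CostTier, money
        cfg = DesignConfig(synthetic_fragment_curve=CostCurve(
            (CostTier(500, money(89), False),)))
        cands = traverse([_mk(0, 400, entry="a")], 1000, cfg)
        assert len(cands) == 1
        c = cands[0]
        assert len(c.matches) == 1
        assert c.fragment_count == 3          # match + 2 synthetic for 600 bp
        assert c.synth_spans[0].fragment_count == 2

    def test_matches_equal_brute_force_enumeration(self, config):
        rng = random.Random(42)
        L = 1000
        for trial in range(8):
            matches = []
            for i in range(rng.randint(2, 7)):
                s = rng.randrange(0, 2 * L - 100)
                e = s + rng.randint(150, 700)
                matches.append(_mk(s, min(e, s + L), entry=f"e{i}"))
            matches.sort(key=lambda m: m.query_start)
            got = {c.signature() for c in traverse(matches, L, config)}
            ref = _brute_force_chains(matches, L, config)
            got_simple = {
                frozenset((x[1], x[2], x[6]) for x in sig if x[0] == "m")
                for sig in got
            }
            assert got_simple == ref, f"trial {trial}"

    def test_output_independent_of_input_order(self, config):
        matches = [_mk(0, 500, entry="a"), _mk(450, 980, entry="b"),
                   _mk(940, 1460, entry="c"), _mk(200, 700, entry="d")]
        fwd = {c.signature() for c in traverse(matches, 1400, config)}
        rev = {c.signature() for c in traverse(matches[::-1], 1400, config)}
        assert fwd == rev

    def test_candidates_satisfy_closure_and_budget(self, config):
        rng = random.Random(7)
        L = 1200
        matches = []
        for i in range(6):
            s = rng.randrange(0, 2 * L - 400)
            matches.append(_mk(s, s + rng.randint(200, 800), entry=f"e{i}"))
        matches.sort(key=lambda m: m.query_start)
        for cand in traverse(matches, L, config):
            assert cand.fragment_count <= config.max_fragment_count
            first = cand.matches[0]
            assert first.query_start < L
            covered_to = cand.matches[-1].query_end
            for span in cand.synth_spans:
                covered_to = max(covered_to, span.gap_end)
            # a small closing gap may ride in primers at the wrap junction
            assert covered_to >= first.query_start + L - config.max_primer_fill_gap

    def test_no_seed_gives_empty_result(self, config):
        assert traverse([_mk(1500, 1900)], 1000, config) == []


def test_all_synthetic_candidate_covers_circle(config):
    cand = all_synthetic_candidate(4000, config)
    assert cand.matches == []
    assert cand.synth_spans[0].gap_start == 0
    assert cand.synth_spans[0].gap_end == 4000
    assert cand.fragment_count == 2     # 4000 bp over a 3000 bp synthesis cap
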