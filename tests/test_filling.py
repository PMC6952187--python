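"""Assembly filling: junction planning, synthesis, screening, Pareto."""

import random
from decimal import Decimal

import pytest

from plasmidplan._seq import circular_slice, revcomp
from plasmidplan.config import CostCurve, CostTier, DesignConfig, money
from plasmidplan.filling import (
    check_ectopic,
    fill,
    make_synthetic,
    pareto_front,
)
from plasmidplan.fixtures import make_palindrome
from plasmidplan.model import (
    BuildFragment,
    CandidateAssembly,
    CostBreakdown,
    FillFailure,
    Match,
    Solution,
    SynthSpan,
)
from plasmidplan.repositories import RepoRecord, Repository
from plasmidplan.thermo import hairpin_tm

from conftest import random_dna


def _target_and_repo(seed, L, spans):
    """A random circle with planted fragments covering the given spans."""
    target = random_dna(seed, L)
    records = {}
    matches = []
    for i, (s, e) in enumerate(spans):
        rid = f"p{i + 1}"
        records[rid] = RepoRecord(rid, circular_slice(target, s, e))
        matches.append(Match("db", rid, s, e, 0, e - s, "+", 100.0))
    repo = Repository(name="db", records=records)
    return target, {"db": repo}, matches


@pytest.fixture
def free_config():
    cfg = DesignConfig()
    return cfg.with_procurement({"db": Decimal("0")})


class TestFillJunctions:
    def test_designed_overlaps_pass_through_unchanged(self, free_config):
        target, repos, matches = _target_and_repo(
            1, 1500, [(0, 520), (470, 1020), (980, 1540)])
        cand = CandidateAssembly(matches=matches, synth_spans=[], L=1500)
        sol = fill(cand, target, free_config, repos)
        assert isinstance(sol, Solution)
        for i, frag in enumerate(sol.fragments):
            nxt = sol.fragments[(i + 1) % 3]
            shift = 1500 if i == 2 else 0
            o = frag.end - (nxt.start + shift)
            assert 15 <= o <= 150

    def test_zero_overlap_deficit_split_between_primer_tails(self, free_config):
        # two abutting PCR fragments: 15 bp deficit -> 8 bp left, 7 bp right
        target, repos, matches = _target_and_repo(
            2, 1200, [(0, 600), (600, 1215)])
        cand = CandidateAssembly(matches=matches, synth_spans=[], L=1200)
        sol = fill(cand, target, free_config, repos)
        assert isinstance(sol, Solution)
        left, right = sol.fragments[0], sol.fragments[1]
        assert left.primers.added_right == 8
        assert right.primers.added_left == 7
        assert left.end - right.start == 15

    def test_excess_overlap_trimmed_to_max_homology(self, free_config):
        target, repos, matches = _target_and_repo(
            3, 1400, [(0, 700), (500, 1430)])   # 200 bp native overlap
        cand = CandidateAssembly(matches=matches, synth_spans=[], L=1400)
        sol = fill(cand, target, free_config, repos)
        assert isinstance(sol, Solution)
        o = sol.fragments[0].end - sol.fragments[1].start
        assert 15 <= o <= 150

    def test_small_gap_embedded_in_primers(self, free_config):
        # 18 bp gap between PCR fragments rides inside the primer tails
        target, repos, matches = _target_and_repo(
            4, 1300, [(0, 640), (658, 1320)])
        cand = CandidateAssembly(matches=matches, synth_spans=[], L=1300)
        sol = fill(cand, target, free_config, repos)
        assert isinstance(sol, Solution)
        left, right = sol.fragments
        assert left.end - right.start >= 15
        gap_and_homology = left.primers.added_right + right.primers.added_left
        assert gap_and_homology == 18 + 15

    def test_gibson_simulation_reconstructs_target(self, free_config):
        from plasmidplan.fixtures import reconstructs
        target, repos, matches = _target_and_repo(
            5, 1600, [(100, 700), (660, 1250), (1210, 1740)])
        cand = CandidateAssembly(matches=matches, synth_spans=[], L=1600)
        sol = fill(cand, target, free_config, repos)
        assert isinstance(sol, Solution)
        assert reconstructs(sol, target)


class TestMakeSynthetic:
    def _curve_config(self, max_len):
        return DesignConfig(synthetic_fragment_curve=CostCurve(
            (CostTier(max_len, money(100), False),)))

    def test_short_span_is_single_fragment(self):
        cfg = self._curve_config(1800)
        target = random_dna(6, 2000)
        frags = make_synthetic(target, 100, 800, cfg)
        assert isinstance(frags, list) and len(frags) == 1
        assert frags[0].sequence == target[100:800]

    def test_oversized_span_split_with_overlaps(self):
        cfg = self._curve_config(1800)
        target = random_dna(7, 3000)
        frags = make_synthetic(target, 0, 2500, cfg)
        assert len(frags) == 2
        lengths = sorted(f.length for f in frags)
        assert abs(lengths[0] - lengths[1]) <= 1
        o = frags[0].end - frags[1].start
        assert o >= cfg.min_homology
        assert frags[0].sequence[-o:] == frags[1].sequence[:o]

    def test_undersized_span_grown_to_minimum(self):
        cfg = self._curve_config(1800)
        target = random_dna(8, 1200)
        frags = make_synthetic(target, 500, 560, cfg)   # 60 bp gap
        assert len(frags) == 1
        assert frags[0].length >= cfg.min_synthetic_length

    def test_palindromic_junction_shifted_or_failed(self):
        cfg = self._curve_config(1000)
        rng = random.Random(9)
        base = random_dna(10, 1800)
        baseline = make_synthetic(base, 0, 1800, cfg)
        assert isinstance(baseline, list)
        junction = baseline[0].end
        pal = make_palindrome(rng, 20)
        hazard = base[:junction - 20] + pal + base[junction:]
        result = make_synthetic(hazard, 0, 1800, cfg)
        if isinstance(result, FillFailure):
            assert result.reason == "hairpin"
        else:
            assert result[0].end != junction        # junction moved
            for frag in result:
                assert hairpin_tm(frag.sequence) <= cfg.max_hairpin_tm


class TestCheckEctopic:
    def test_duplicated_site_fails_with_duplex_tm(self, free_config):
        primer = random_dna(11, 22)
        source = random_dna(12, 400) + primer + random_dna(13, 200)
        hit = check_ectopic(primer, [("db", "rec", source)], free_config)
        assert hit is not None
        site, tm = hit
        from plasmidplan.thermo import binding_tm
        assert tm == pytest.approx(binding_tm(primer))

    def test_unique_primer_passes(self, free_config):
        primer = random_dna(14, 22)
        source = random_dna(15, 800)
        assert check_ectopic(primer, [("db", "rec", source)], free_config) is None

    def test_three_prime_mismatch_site_passes(self, free_config):
        primer = random_dna(16, 22)
        decoy = primer[:-2] + ("AA" if primer[-1] != "A" else "CC")
        source = random_dna(17, 300) + decoy + random_dna(18, 300)
        assert check_ectopic(primer, [("db", "rec", source)], free_config) is None

    def test_intended_span_not_flagged(self, free_config):
        primer = random_dna(19, 22)
        source = random_dna(20, 100) + primer + random_dna(21, 400)
        intended = [("db", "rec", 100, 122 + 50)]
        assert check_ectopic(primer, [("db", "rec", source)], free_config,
                             intended=intended) is None

    def test_reverse_strand_duplicate_detected(self, free_config):
        primer = random_dna(22, 22)
        source = random_dna(23, 300) + revcomp(primer) + random_dna(24, 300)
        assert check_ectopic(primer, [("db", "rec", source)],
                             free_config) is not None


class TestParetoFront:
    def _sol(self, cost, count):
        bd = CostBreakdown()
        bd.add("synthesis", "x", money(cost))
        frags = [BuildFragment(id=f"f{i}", kind="synthetic", sequence="A" * 200,
                               start=0, end=200) for i in range(count)]
        return Solution(fragments=frags, cost=bd)

    def test_dominated_solution_dropped(self):
        sols = [self._sol(100, 4), self._sol(120, 3), self._sol(130, 5)]
        front = pareto_front(sols)
        assert [(int(s.total), s.fragment_count) for s in front] == \
            [(100, 4), (120, 3)]

    def test_single_solution_is_its_own_front(self):
        sols = [self._sol(99, 2)]
        assert pareto_front(sols) == sols

    def test_equal_cost_keeps_fewer_fragments(self):
        front = pareto_front([self._sol(100, 3), self._sol(100, 4)])
        assert len(front) == 1 and front[0].fragment_count == 3

    def test_front_is_an_antichain(self):
        rng = random.Random(25)
        sols = [self._sol(rng.randint(50, 500), rng.randint(1, 6))
                for _ in range(30)]
        front = pareto_front(sols)
        for a in front:
            for b in front:
                if a is not b:
                    assert not (a.total <= b.total and
                                a.fragment_count <= b.fragment_count)
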