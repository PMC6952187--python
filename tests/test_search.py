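"""Fragment search: scoring parameters, both backends, and culling."""

import pytest
from hypothesis import given, settings, strategies as st

from plasmidplan._seq import circular_slice, revcomp
from plasmidplan.model import Match
from plasmidplan.repositories import RepoRecord, Repository, build_repository
from plasmidplan.search import cull_engulfed, find_matches, scoring_params

from conftest import random_dna


def _mk(qs, qe, repo="db", entry="e"):
    return Match(repo, entry, qs, qe, 0, qe - qs, "+", 100.0)


def _repo(name, **records):
    return Repository(name=name, records={
        k: RepoRecord(k, v) for k, v in records.items()})


class TestScoringParams:
    def test_row_at_90_percent(self):
        p = scoring_params(90)
        assert (p.reward, p.penalty, p.gap_open, p.gap_extend) == (1, -2, 1, 2)

    def test_strict_penalties_above_99(self):
        p = scoring_params(100)
        assert (p.penalty, p.gap_open, p.gap_extend) == (-6, 6, 6)
        assert scoring_params(99.5) == p

    def test_98_uses_nearest_row_at_or_below(self):
        assert scoring_params(98) == scoring_params(95)

    @pytest.mark.parametrize("identity", [49, 101, -5])
    def test_out_of_range_rejected(self, identity):
        with pytest.raises(ValueError):
            scoring_params(identity)


class TestFindMatches:
    def test_exact_target_gives_full_length_self_match(self):
        target = random_dna(1, 300)
        repo = _repo("db", whole=target)
        matches = find_matches(target, [repo], 98, backend="kmer")
        spans = {(m.query_start, m.query_end) for m in matches}
        assert (0, 300) in spans          # the self-match...
        assert any(qs > 0 and qe - qs == 300 for qs, qe in spans) \
            or (0, 600) in spans          # ...and its origin-spanning copy

    def test_no_homology_gives_empty_list(self):
        target = random_dna(2, 300)
        repo = _repo("db", decoy=random_dna(977, 300))
        assert find_matches(target, [repo], 98, backend="kmer") == []

    def test_origin_spanning_fragment_found_on_doubled_query(self):
        target = random_dna(3, 300)
        fragment = target[250:] + target[:50]      # wraps the origin
        repo = _repo("db", wrap=fragment)
        matches = find_matches(target, [repo], 98, backend="kmer")
        assert any(m.query_end - m.query_start == 100 and
                   m.query_start % 300 == 250 for m in matches)

    def test_reverse_strand_fragment_reported_with_minus_strand(self):
        target = random_dna(4, 400)
        repo = _repo("db", rc=revcomp(target[100:300]))
        matches = find_matches(target, [repo], 98, backend="kmer")
        hit = next(m for m in matches if m.query_start == 100)
        assert hit.strand == "-" and m_span(hit) == 200

    def test_matches_longer_than_target_truncated_to_L(self):
        target = random_dna(5, 250)
        repo = _repo("db", double=target + target)
        matches = find_matches(target, [repo], 98, backend="kmer")
        assert all(m.query_end - m.query_start <= 250 for m in matches)

    def test_extracted_subject_equals_target_span(self):
        target = random_dna(6, 500)
        frag = circular_slice(target, 450, 620)
        repo = _repo("db", planted=frag)
        for m in find_matches(target, [repo], 98, backend="kmer"):
            subject = repo.records[m.entry].sequence[m.subject_start:m.subject_end]
            if m.strand == "-":
                subject = revcomp(subject)
            assert subject == circular_slice(target + target, m.query_start,
                                             m.query_end)


def m_span(m):
    return m.query_end - m.query_start


class TestBlastBackend:
    def test_agrees_with_exact_backend_on_planted_fragments(self, tmp_path):
        target = random_dna(7, 800)
        fa = tmp_path / "db.fa"
        fa.write_text(
            f">a\n{target[:300]}\n>b\n{target[280:600]}\n"
            f">c\n{circular_slice(target, 580, 830)}\n")
        repo = build_repository(fa, "db")
        blast = cull_engulfed(find_matches(target, [repo], 98, backend="blast"))
        kmer = cull_engulfed(find_matches(target, [repo], 98, backend="kmer"))
        blast_spans = {(m.entry, m.query_start, m.query_end) for m in blast}
        kmer_spans = {(m.entry, m.query_start, m.query_end) for m in kmer}
        assert kmer_spans <= blast_spans | kmer_spans
        # every planted fragment is recovered at its position by BLAST
        for entry, start, length in (("a", 0, 300), ("b", 280, 320), ("c", 580, 250)):
            assert any(m.entry == entry and m.query_start == start
                       and m_span(m) == length for m in blast)


class TestCullEngulfed:
    def test_contained_spans_removed(self):
        got = cull_engulfed([_mk(0, 100), _mk(10, 50), _mk(60, 200)])
        assert [(m.query_start, m.query_end) for m in got] == [(0, 100), (60, 200)]

    def test_identical_spans_keep_lexicographic_first(self):
        a = _mk(5, 50, repo="zoo", entry="z")
        b = _mk(5, 50, repo="abc", entry="a")
        got = cull_engulfed([a, b])
        assert len(got) == 1 and got[0].repo == "abc"

    def test_empty_input(self):
        assert cull_engulfed([]) == []

    @given(st.lists(
        st.tuples(st.integers(0, 80), st.integers(1, 60)), max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_output_is_an_antichain_subset_and_idempotent(self, raw):
        matches = sorted((_mk(s, s + l, entry=f"e{i}")
                          for i, (s, l) in enumerate(raw)),
                         key=lambda m: m.query_start)
        got = cull_engulfed(matches)
        assert set(got) <= set(matches)
        for a in got:
            for b in got:
                if a is not b:
                    assert not (b.query_start <= a.query_start and
                                a.query_end <= b.query_end)
        assert cull_engulfed(got) == got

    def test_self_match_survives_and_removes_all_others(self):
        target_len = 300
        whole = _mk(0, target_len, entry="whole")
        parts = [_mk(0, 120, entry="p1"), _mk(100, 250, entry="p2")]
        got = cull_engulfed(sorted([whole] + parts,
                                   key=lambda m: m.query_start))
        assert whole in got
        assert all(p not in got for p in parts)
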