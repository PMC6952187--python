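"""Assembly filling: turn candidate assemblies into concrete solutions.

Filling resolves every junction to an exact homology overlap of
[min_homology, max_homology] bp, designs primers (junction homology and
small sequence gaps ride as 5' primer tails), screens primers for ectopic
binding sites in the build's source plasmids, materializes synthetic
fragments (splitting oversized spans, dodging hairpins at 3' ends), and
prices the result. A failure at any stage is returned as a typed value so
the driver can move on to the next candidate; survivors are reduced to
the Pareto-optimal set under (cost, fragment count).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import thermo
from ._seq import circular_slice, revcomp
from .config import DesignConfig, assembly_cost
from .model import (
    BuildFragment,
    CandidateAssembly,
    FillFailure,
    Match,
    Solution,
)
from .primers import PrimerDesignError, design_primers
from .repositories import Repository

log = logging.getLogger(__name__)

HAIRPIN_STRIDE = 5
HAIRPIN_RETRIES = 10
EXISTING_COVERAGE = 0.999   # match fraction of L (and of its record) that
                            # counts as an already-existing plasmid
_MIN_KEEP = 30              # never trim a fragment below this many bp


@dataclass
class _Plan:
    kind: str                      # 'pcr' | 'synthetic'
    start: int                     # native span on the (doubled) target axis
    end: int
    match: Optional[Match] = None
    ext_left: int = 0              # target-axis bp added beyond the span
    ext_right: int = 0
    sub_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def final_start(self) -> int:
        return self.start - self.ext_left

    @property
    def final_end(self) -> int:
        return self.end + self.ext_right

    @property
    def final_length(self) -> int:
        return self.final_end - self.final_start


def fill(candidate: CandidateAssembly, target: str, config: DesignConfig,
         repos: Optional[dict[str, Repository]] = None,
         check_ectopic_sites: bool = True) -> Solution | FillFailure:
    """Fill one candidate assembly against the circular target."""
    L = len(target)
    repos = repos or {}

    existing = _as_existing(candidate, L, repos)
    if existing is not None:
        return _priced(existing, config)

    plans = _build_plans(candidate, config)
    if isinstance(plans, FillFailure):
        return plans
    failure = _plan_junctions(plans, L, config)
    if failure is not None:
        return failure
    failure = _grow_small_synthetics(plans, L, config)
    if failure is not None:
        return failure
    failure = _split_synthetics(plans, config)
    if failure is not None:
        return failure
    failure = _avoid_hairpins(plans, target, L, config)
    if failure is not None:
        return failure

    fragments, failure = _materialize(plans, target, L, config, repos,
                                      check_ectopic_sites)
    if failure is not None:
        return failure
    if len(fragments) > config.max_fragment_count:
        return FillFailure("limit", f"{len(fragments)} fragments exceed the limit")
    failure = _validate_junctions(fragments, L, config)
    if failure is not None:
        return failure
    return _priced(fragments, config)


def _priced(fragments: list[BuildFragment], config: DesignConfig) -> Solution:
    sol = Solution(fragments=fragments, cost=None)  # type: ignore[arg-type]
    sol.cost = assembly_cost(sol, config)
    return sol


# --------------------------------------------------------------------------
# existing whole-plasmid shortcut


def _as_existing(candidate: CandidateAssembly, L: int,
                 repos: dict[str, Repository]) -> Optional[list[BuildFragment]]:
    if len(candidate.matches) != 1 or candidate.synth_spans:
        return None
    m = candidate.matches[0]
    if m.length < EXISTING_COVERAGE * L:
        return None
    repo = repos.get(m.repo)
    record_len = len(repo.records[m.entry].sequence) if repo and m.entry in repo.records \
        else None
    if record_len is not None and (m.subject_end - m.subject_start) \
            < EXISTING_COVERAGE * record_len:
        return None  # the target is a sub-span of a larger plasmid: PCR it
    sequence = repo.records[m.entry].sequence if record_len is not None else ""
    return [BuildFragment(
        id="f1", kind="existing", sequence=sequence,
        start=m.query_start, end=m.query_end,
        repo=m.repo, entry=m.entry, subject_start=m.subject_start,
        subject_end=m.subject_end, strand=m.strand)]


# --------------------------------------------------------------------------
# plan construction and junction resolution


def _build_plans(candidate: CandidateAssembly,
                 config: DesignConfig) -> list[_Plan] | FillFailure:
    plans: list[_Plan] = []
    for m in candidate.matches:
        plans.append(_Plan("pcr", m.query_start, m.query_end, match=m))
    for span in candidate.synth_spans:
        plans.append(_Plan("synthetic", span.gap_start, span.gap_end))
    plans.sort(key=lambda p: (p.start, p.end))
    if not plans:
        return FillFailure("junction", "empty candidate")
    return plans


def _plan_junctions(plans: list[_Plan], L: int,
                    config: DesignConfig) -> Optional[FillFailure]:
    """Resolve every cyclic junction to an overlap in [min, max] homology.

    Deficits are added as extensions whose sequence comes from the target:
    split ceil-left/floor-right between two PCR fragments, carried wholly
    by the synthetic side when one side is synthetic. Excess overlap trims
    the later (3') fragment first.
    """
    n = len(plans)
    for i in range(n):
        left = plans[i]
        right = plans[(i + 1) % n]
        shift = L if i == n - 1 else 0
        o = left.end - (right.start + shift)
        if o > config.max_homology:
            trim = o - config.max_homology
            give_r = min(trim, max(0, (right.end - right.start) - _MIN_KEEP))
            give_l = trim - give_r
            if give_l > max(0, (left.end - left.start) - _MIN_KEEP):
                return FillFailure(
                    "junction", f"cannot trim {o} bp overlap at junction {i}")
            right.start += give_r
            left.end -= give_l
            _shift_subject(right, trim_start=give_r)
            _shift_subject(left, trim_end=give_l)
            o = left.end - (right.start + shift)
        if o < config.min_homology:
            gap = -o
            if gap > config.max_primer_fill_gap:
                return FillFailure(
                    "junction",
                    f"{gap} bp gap at junction {i} exceeds the primer-fill limit")
            deficit = config.min_homology - o
            if left.kind == "synthetic" and right.kind != "synthetic":
                left.ext_right += deficit
            elif right.kind == "synthetic" and left.kind != "synthetic":
                right.ext_left += deficit
            else:
                left.ext_right += math.ceil(deficit / 2)
                right.ext_left += deficit - math.ceil(deficit / 2)
    return None


def _shift_subject(plan: _Plan, trim_start: int = 0, trim_end: int = 0) -> None:
    """Keep a PCR plan's subject span aligned with its trimmed query span."""
    m = plan.match
    if m is None or (trim_start == 0 and trim_end == 0):
        return
    if m.strand == "+":
        ss, se = m.subject_start + trim_start, m.subject_end - trim_end
    else:
        ss, se = m.subject_start + trim_end, m.subject_end - trim_start
    plan.match = Match(m.repo, m.entry, m.query_start + trim_start,
                       m.query_end - trim_end, ss, se, m.strand, m.identity)


def _junction_overlap(plans: list[_Plan], i: int, L: int) -> int:
    left = plans[i]
    right = plans[(i + 1) % len(plans)]
    shift = L if i == len(plans) - 1 else 0
    return left.final_end - (right.final_start + shift)


def _grow_small_synthetics(plans: list[_Plan], L: int,
                           config: DesignConfig) -> Optional[FillFailure]:
    """Grow undersized synthetic fragments symmetrically into neighboring
    homology, never pushing a junction past max_homology."""
    n = len(plans)
    for i, plan in enumerate(plans):
        if plan.kind != "synthetic":
            continue
        short = config.min_synthetic_length - plan.final_length
        if short <= 0:
            continue
        left_j = (i - 1) % n
        room_left = config.max_homology - _junction_overlap(plans, left_j, L)
        room_right = config.max_homology - _junction_overlap(plans, i, L)
        grow_left = min(math.ceil(short / 2), max(0, room_left))
        grow_right = min(short - grow_left, max(0, room_right))
        if grow_left + grow_right < short:
            grow_left = min(short - grow_right, max(0, room_left))
        if grow_left + grow_right < short:
            return FillFailure(
                "junction",
                f"synthetic span at {plan.start} cannot reach "
                f"{config.min_synthetic_length} bp within homology limits")
        plan.ext_left += grow_left
        plan.ext_right += grow_right
    return None


def _avoid_hairpins(plans: list[_Plan], target: str, L: int,
                    config: DesignConfig) -> Optional[FillFailure]:
    """Shift synthetic 3' junctions off predicted hairpins.

    Every synthetic sub-fragment's 3' end is folded; while the predicted
    hairpin Tm exceeds the ceiling, the 3' end is extended in strides into
    the downstream homology (internal sub-junction or the outer junction),
    re-checking after each extension, until either the hairpin clears or
    the homology cap / retry budget is exhausted.
    """
    for i, plan in enumerate(plans):
        if plan.kind != "synthetic":
            continue
        spans = plan.sub_spans or [(plan.final_start, plan.final_end)]
        for j in range(len(spans)):
            s, e = spans[j]
            for attempt in range(HAIRPIN_RETRIES + 1):
                tm = thermo.hairpin_tm(circular_slice(target, s, e))
                if tm <= config.max_hairpin_tm:
                    break
                last = j == len(spans) - 1
                if last:
                    overlap = _junction_overlap(plans, i, L)
                else:
                    overlap = e - spans[j + 1][0]
                if attempt == HAIRPIN_RETRIES \
                        or overlap + HAIRPIN_STRIDE > config.max_homology \
                        or e - s + HAIRPIN_STRIDE > config.max_synthetic_length:
                    return FillFailure(
                        "hairpin",
                        f"synthetic span [{plan.start}, {plan.end}) keeps a "
                        f"hairpin of {tm:.1f} °C at a 3' end")
                e += HAIRPIN_STRIDE
                if last:
                    plan.ext_right += HAIRPIN_STRIDE
            spans[j] = (s, e)
        plan.sub_spans = spans
    return None


def _split_synthetics(plans: list[_Plan],
                      config: DesignConfig) -> Optional[FillFailure]:
    """Split oversized synthetic plans into near-equal sub-fragments that
    share min_homology overlaps."""
    h = config.min_homology
    for plan in plans:
        if plan.kind != "synthetic":
            continue
        total = plan.final_length
        if total <= config.max_synthetic_length:
            plan.sub_spans = [(plan.final_start, plan.final_end)]
            continue
        q = math.ceil(total / config.max_synthetic_length)
        while math.ceil((total + (q - 1) * h) / q) > config.max_synthetic_length:
            q += 1
        stretched = total + (q - 1) * h
        base = stretched // q
        extra = stretched % q
        spans = []
        pos = plan.final_start
        for i in range(q):
            length = base + (1 if i < extra else 0)
            spans.append((pos, pos + length))
            pos += length - h
        spans[-1] = (spans[-1][0], plan.final_end)
        plan.sub_spans = spans
    return None


# --------------------------------------------------------------------------
# materialization: sequences, primers, ectopic screening


def _materialize(plans: list[_Plan], target: str, L: int, config: DesignConfig,
                 repos: dict[str, Repository], check_sites: bool
                 ) -> tuple[list[BuildFragment], Optional[FillFailure]]:
    n = len(plans)
    start_slack = [0] * n
    end_slack = [0] * n
    for j in range(n):
        left, right = plans[j], plans[(j + 1) % n]
        slack = max(0, _junction_overlap(plans, j, L) - config.min_homology)
        if slack == 0:
            continue
        if left.kind == "pcr" and right.kind == "pcr":
            end_slack[j] = slack // 2
            start_slack[(j + 1) % n] = slack - slack // 2
        elif left.kind == "pcr":
            end_slack[j] = slack
        elif right.kind == "pcr":
            start_slack[(j + 1) % n] = slack

    fragments: list[BuildFragment] = []
    for i, plan in enumerate(plans):
        if plan.kind == "pcr":
            frag_id = f"f{len(fragments) + 1}"
            amplicon = circular_slice(target, plan.final_start, plan.final_end)
            try:
                pair = design_primers(amplicon, plan.ext_left, plan.ext_right,
                                      frag_id, left_slack=start_slack[i],
                                      right_slack=end_slack[i])
            except PrimerDesignError as exc:
                return [], FillFailure("primer", str(exc))
            dl, dr = pair.trim_left, pair.trim_right
            m = plan.match
            if m.strand == "+":
                ss, se = m.subject_start + dl, m.subject_end - dr
            else:
                ss, se = m.subject_start + dr, m.subject_end - dl
            fragments.append(BuildFragment(
                id=frag_id, kind="pcr",
                sequence=amplicon[dl:len(amplicon) - dr or None],
                start=plan.final_start + dl, end=plan.final_end - dr,
                repo=m.repo, entry=m.entry, subject_start=ss,
                subject_end=se, strand=m.strand, primers=pair))
        else:
            for s, e in plan.sub_spans or [(plan.final_start, plan.final_end)]:
                frag_id = f"f{len(fragments) + 1}"
                fragments.append(BuildFragment(
                    id=frag_id, kind="synthetic",
                    sequence=circular_slice(target, s, e), start=s, end=e))
    fragments.sort(key=lambda f: f.start)
    for i, frag in enumerate(fragments):
        frag.id = f"f{i + 1}"

    if check_sites:
        sources = _source_sequences(fragments, repos)
        intended = [(f.repo, f.entry, f.subject_start, f.subject_end)
                    for f in fragments if f.repo is not None]
        for frag in fragments:
            if frag.primers is None:
                continue
            for which, primer in (("fwd", frag.primers.fwd),
                                  ("rev", frag.primers.rev)):
                hit = check_ectopic(primer, sources, config, intended=intended)
                if hit is not None:
                    site, tm = hit
                    return [], FillFailure(
                        "ectopic",
                        f"{frag.id} {which} primer has an ectopic site at "
                        f"{site} with predicted Tm {tm:.1f} °C")
    return fragments, None


def _source_sequences(fragments: list[BuildFragment],
                      repos: dict[str, Repository]) -> list[tuple[str, str, str]]:
    out = []
    seen = set()
    for frag in fragments:
        if frag.repo is None or frag.entry is None:
            continue
        key = (frag.repo, frag.entry)
        if key in seen:
            continue
        seen.add(key)
        repo = repos.get(frag.repo)
        if repo is not None and frag.entry in repo.records:
            out.append((frag.repo, frag.entry, repo.records[frag.entry].sequence))
    return out


def check_ectopic(primer: str, sources: list[tuple[str, str, str]],
                  config: DesignConfig,
                  intended: Optional[list[tuple]] = None,
                  min_identity: float = 0.65
                  ) -> Optional[tuple[str, float]]:
    """Screen one primer against the build's source plasmids.

    Scans both strands of every source for windows matching the primer at
    >= 65% identity; each hit gets an end-anchored duplex Tm, and the
    first site exceeding the configured ceiling is returned as
    ``(location, tm)``. ``None`` means the primer passed.

    ``intended`` lists the build's amplified subject spans as
    ``(repo, entry, subject_start, subject_end)``; hits inside them are
    material the design deliberately amplifies (binding sites, shared
    junction homology) and are not ectopic.
    """
    p = np.frombuffer(primer.upper().encode(), dtype=np.uint8)
    m = len(p)
    if m == 0:
        return None
    intended = intended or []
    for repo, entry, seq in sources:
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            if len(arr) < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, m)
            identity = (windows == p).mean(axis=1)
            for pos in np.nonzero(identity >= min_identity)[0]:
                start = int(pos)
                if strand == "-":
                    fwd_start = len(seq) - start - m
                else:
                    fwd_start = start
                if any(r == repo and e == entry and ss is not None
                       and fwd_start < se and fwd_start + m > ss
                       for r, e, ss, se in intended):
                    continue  # within an amplified span: not ectopic
                site = s[start:start + m]
                tm = thermo.ectopic_duplex_tm(primer, site)
                if tm > config.max_ectopic_tm:
                    return (f"{repo}:{entry}:{fwd_start}{strand}", tm)
    return None


def make_synthetic(target: str, start: int, end: int, config: DesignConfig
                   ) -> list[BuildFragment] | FillFailure:
    """Materialize a standalone synthetic span of the target circle.

    Applies the full synthetic pipeline: growth to the minimum orderable
    length, near-equal splitting with min_homology overlaps when the span
    exceeds the maximum synthesis length, and hairpin avoidance at every
    3' end.
    """
    if end - start <= config.max_primer_fill_gap:
        raise ValueError("span small enough to embed in primers")
    plan = _Plan("synthetic", start, end)
    plans = [plan]
    L = len(target)
    for step in (lambda: _grow_small_synthetics(plans, L, config),
                 lambda: _split_synthetics(plans, config),
                 lambda: _avoid_hairpins(plans, target, L, config)):
        failure = step()
        if failure is not None:
            return failure
    fragments = []
    for i, (s, e) in enumerate(plan.sub_spans):
        fragments.append(BuildFragment(
            id=f"s{i + 1}", kind="synthetic",
            sequence=circular_slice(target, s, e), start=s, end=e))
    return fragments


# --------------------------------------------------------------------------
# junction validation and the Pareto front


def _validate_junctions(fragments: list[BuildFragment], L: int,
                        config: DesignConfig) -> Optional[FillFailure]:
    n = len(fragments)
    for i in range(n):
        left, right = fragments[i], fragments[(i + 1) % n]
        shift = L if i == n - 1 else 0
        o = left.end - (right.start + shift)
        if not config.min_homology <= o <= config.max_homology:
            return FillFailure(
                "junction", f"junction {left.id}->{right.id} overlap {o} bp "
                f"outside [{config.min_homology}, {config.max_homology}]")
        if left.sequence[-o:] != right.sequence[:o]:
            return FillFailure(
                "junction", f"junction {left.id}->{right.id} is not exact")
    return None


def pareto_front(solutions: list[Solution]) -> list[Solution]:
    """The antichain of solutions under (cost, fragment_count) dominance,
    ascending by cost; equal-cost solutions keep the fewest fragments."""
    ordered = sorted(solutions, key=lambda s: (s.total, s.fragment_count))
    kept: list[Solution] = []
    for sol in ordered:
        if any(k.total <= sol.total and k.fragment_count <= sol.fragment_count
               for k in kept):
            continue
        kept.append(sol)
    return kept


def fill_candidates(candidates: list[CandidateAssembly], target: str,
                    config: DesignConfig,
                    repos: Optional[dict[str, Repository]] = None,
                    check_ectopic_sites: bool = True
                    ) -> tuple[list[Solution], list[FillFailure]]:
    """Fill candidates in ascending (estimated cost, fragment count) order,
    skipping any whose cost lower bound is already dominated by a filled
    solution, and return the Pareto front plus the failures seen."""
    ordered = sorted(candidates,
                     key=lambda c: (c.estimated_cost, c.fragment_count))
    kept: list[Solution] = []
    failures: list[FillFailure] = []
    for cand in ordered:
        if any(k.total <= cand.lower_bound_cost
               and k.fragment_count <= cand.fragment_count for k in kept):
            continue
        result = fill(cand, target, config, repos, check_ectopic_sites)
        if isinstance(result, FillFailure):
            failures.append(result)
            continue
        kept.append(result)
    return pareto_front(kept), failures
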