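"""Synthetic design instances with known ground truth, plus the two
oracles that anchor the test suite: simulated Gibson reconstruction and
brute-force minimum-cost design.

Fixture targets are seeded random circles; repository records are spans
of the target planted with designed junction overlaps (and optional
hazards: an origin-spanning fragment, a duplicated primer site, a
palindrome at a junction), padded with decoy records drawn from an
independent random stream and screened so they share no 15-mer with the
target.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import Optional

from ._seq import circular_slice, revcomp, rotations_equal
from .config import DesignConfig
from .filling import fill, pareto_front
from .model import CandidateAssembly, Match, PlasmidPlanError, Solution, SynthSpan
from .repositories import RepoRecord, Repository

_DECOY_SALT = 0x9E3779B9
_ALPHABET = "ACGT"


class FixtureError(PlasmidPlanError):
    pass


class SimulatedAssemblyError(PlasmidPlanError):
    """A junction failed the 15-150 bp exact-overlap validity rule."""


@dataclass
class FixtureSpec:
    target_length: int
    layout: list[tuple[int, int, str]]       # (start, end, repo) on the circle
    decoys: int = 2
    decoy_length: tuple[int, int] = (300, 900)
    origin_spanning: bool = False
    duplicated_primer_site: bool = False
    palindrome_at: Optional[int] = None
    rng_seed: int = 0

    def validate(self) -> None:
        L = self.target_length
        if not self.layout:
            return
        spans = sorted(self.layout)
        for start, end, _repo in spans:
            if not 0 <= start < L or not start < end <= start + L:
                raise FixtureError(f"bad layout span ({start}, {end})")


@dataclass
class Fixture:
    spec: FixtureSpec
    target: str
    repositories: dict[str, Repository]
    manifest: dict


def random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_ALPHABET) for _ in range(length))


def make_palindrome(rng: random.Random, length: int = 20) -> str:
    half = random_sequence(rng, length // 2)
    return half + revcomp(half)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Materialize a fixture: seeded target, planted repository fragments,
    independent decoys, and a manifest recording the intended solution."""
    spec.validate()
    rng = random.Random(spec.rng_seed)
    L = spec.target_length
    target = list(random_sequence(rng, L))

    if spec.palindrome_at is not None:
        pal = make_palindrome(rng)
        for i, ch in enumerate(pal):
            target[(spec.palindrome_at + i) % L] = ch
    target_str = "".join(target)

    repo_records: dict[str, dict[str, RepoRecord]] = {}
    planted = []
    for idx, (start, end, repo) in enumerate(spec.layout):
        frag = circular_slice(target_str, start, end)
        rec_id = f"planted{idx + 1}"
        seq = frag
        if spec.duplicated_primer_site and idx == 0:
            # replicate the fragment's 5' primer site elsewhere in the record
            spacer_rng = random.Random(spec.rng_seed ^ 0xD1CE)
            seq = frag + random_sequence(spacer_rng, 60) + frag[:30]
        repo_records.setdefault(repo, {})[rec_id] = RepoRecord(rec_id, seq)
        planted.append({"record": rec_id, "repo": repo,
                        "start": start, "end": end})

    decoy_rng = random.Random(spec.rng_seed ^ _DECOY_SALT)
    kmers = {target_str[i:i + 15] for i in range(L - 14)}
    doubled = target_str + target_str[:14]
    kmers |= {doubled[i:i + 15] for i in range(L - 14, L)}
    kmers |= {revcomp(k) for k in set(kmers)}
    default_repo = spec.layout[0][2] if spec.layout else "userdb"
    for d in range(spec.decoys):
        length = decoy_rng.randint(*spec.decoy_length)
        for _attempt in range(20):
            seq = random_sequence(decoy_rng, length)
            if not any(seq[i:i + 15] in kmers for i in range(len(seq) - 14)):
                break
        else:
            raise FixtureError("could not draw a homology-free decoy")
        repo_records.setdefault(default_repo, {})[f"decoy{d + 1}"] = \
            RepoRecord(f"decoy{d + 1}", seq)

    repositories = {
        name: Repository(name=name, records=records)
        for name, records in repo_records.items()
    }
    manifest = {
        "seed": spec.rng_seed,
        "target_length": L,
        "planted": planted,
        "decoys": spec.decoys,
        "hazards": {
            "origin_spanning": spec.origin_spanning,
            "duplicated_primer_site": spec.duplicated_primer_site,
            "palindrome_at": spec.palindrome_at,
        },
    }
    return Fixture(spec=spec, target=target_str,
                   repositories=repositories, manifest=manifest)


def random_fixture_spec(seed: int, allow_gaps: bool = True,
                        repo: str = "userdb") -> FixtureSpec:
    """A randomized valid fixture layout: 2-4 planted fragments covering
    the circle with designed 18-60 bp junction overlaps, optionally one
    30-300 bp gap left for synthesis."""
    rng = random.Random(seed)
    L = rng.randint(1200, 2600)
    n = rng.randint(2, min(4, L // 420))
    while True:
        cuts = sorted(rng.sample(range(L), n))
        if all(((cuts[(i + 1) % n] - cuts[i]) % L or L) >= 360 for i in range(n)):
            break
    gap_junction = rng.randrange(n) if (allow_gaps and rng.random() < 0.5) \
        else None
    layout = []
    for i in range(n):
        start = cuts[i]
        arc = (cuts[(i + 1) % n] - cuts[i]) % L or L
        if gap_junction == (i + 1) % n:
            gap = rng.randint(30, min(300, arc - 320))
            end = start + arc - gap
        else:
            end = start + arc + rng.randint(18, 60)
        layout.append((start, end, repo))
    origin_spanning = layout[-1][1] > L
    return FixtureSpec(target_length=L, layout=layout, decoys=2,
                       origin_spanning=origin_spanning, rng_seed=seed)


# --------------------------------------------------------------------------
# oracle 1: simulated Gibson assembly


def _max_suffix_prefix(left: str, right: str, cap: int) -> int:
    for o in range(min(cap, len(left), len(right)), 0, -1):
        if left[-o:] == right[:o]:
            return o
    return 0


def simulate_gibson(fragments: list[str], min_overlap: int = 15,
                    max_overlap: int = 150) -> str:
    """Assemble fragments in the given cyclic order via their maximal
    exact suffix-prefix overlaps; every junction must overlap within
    [min_overlap, max_overlap] or :class:`SimulatedAssemblyError` names
    the junction. A single fragment self-circularizes. Returns the
    circular product."""
    if not fragments:
        raise ValueError("need at least one fragment")
    n = len(fragments)
    overlaps = []
    for i in range(n):
        left = fragments[i]
        right = fragments[(i + 1) % n]
        cap = min(len(left), len(right)) - (1 if n == 1 else 0)
        o = _max_suffix_prefix(left, right, cap)
        if not min_overlap <= o <= max_overlap:
            raise SimulatedAssemblyError(
                f"junction {i}->{(i + 1) % n}: overlap {o} bp outside "
                f"[{min_overlap}, {max_overlap}]")
        overlaps.append(o)
    if n == 1:
        return fragments[0][:-overlaps[0]]
    merged = fragments[0]
    for i in range(1, n):
        merged += fragments[i][overlaps[i - 1]:]
    closing = overlaps[-1]
    return merged[:-closing] if closing else merged


def reconstructs(solution: Solution, target: str) -> bool:
    """True when simulated assembly of the solution's fragments equals the
    target circle up to rotation (an existing whole plasmid must simply
    match the target)."""
    frags = [f.sequence for f in solution.fragments]
    if len(frags) == 1 and solution.fragments[0].kind == "existing":
        return rotations_equal(frags[0], target) or \
            len(frags[0]) >= len(target)
    try:
        product = simulate_gibson(frags)
    except SimulatedAssemblyError:
        return False
    return rotations_equal(product, target)


# --------------------------------------------------------------------------
# oracle 2: brute-force minimum-cost design


def brute_force_design(matches: list[Match], target: str,
                       config: DesignConfig,
                       repos: Optional[dict[str, Repository]] = None
                       ) -> tuple[Optional[Solution], list[Solution]]:
    """Exhaustively fill every closing chain (and the all-synthetic
    design) and return (cheapest solution, full Pareto antichain).

    Enumeration is exponential; refuses more than 12 matches.
    """
    if len(matches) > 12:
        raise FixtureError(f"too many matches for brute force ({len(matches)})")
    L = len(target)
    ordered = sorted(matches, key=lambda m: (m.query_start, m.query_end))
    solutions: list[Solution] = []
    for r in range(1, len(ordered) + 1):
        for combo in itertools.combinations(ordered, r):
            cand = _chain_candidate(list(combo), L, config)
            if cand is None:
                continue
            result = fill(cand, target, config, repos)
            if isinstance(result, Solution):
                solutions.append(result)
    synth = _all_synth_candidate(L, config)
    result = fill(synth, target, config, repos)
    if isinstance(result, Solution):
        solutions.append(result)
    if not solutions:
        return None, []
    front = pareto_front(solutions)
    cheapest = min(solutions, key=lambda s: (s.total, s.fragment_count))
    return cheapest, front


def _chain_candidate(chain: list[Match], L: int,
                     config: DesignConfig) -> Optional[CandidateAssembly]:
    first = chain[0]
    if first.query_start >= L:
        return None
    starts = [m.query_start for m in chain]
    if starts != sorted(set(starts)) or len(set(starts)) != len(chain):
        return None
    close_at = first.query_start + L
    spans = []
    prev_end = None
    for m in chain:
        if m.query_start >= close_at:
            return None
        if prev_end is not None:
            gap = m.query_start - prev_end
            if gap > config.max_primer_fill_gap:
                count = math.ceil(gap / config.max_synthetic_length)
                spans.append(SynthSpan(prev_end, m.query_start, count))
            elif gap > 0:
                pass  # primer-embedded
        prev_end = m.query_end
    closing_gap = close_at - chain[-1].query_end
    if closing_gap > config.max_primer_fill_gap:
        count = math.ceil(closing_gap / config.max_synthetic_length)
        spans.append(SynthSpan(chain[-1].query_end, close_at, count))
    cand = CandidateAssembly(matches=chain, synth_spans=spans, L=L)
    if cand.fragment_count > config.max_fragment_count:
        return None
    return cand


def _all_synth_candidate(L: int, config: DesignConfig) -> CandidateAssembly:
    count = max(1, math.ceil(L / config.max_synthetic_length))
    return CandidateAssembly(matches=[],
                             synth_spans=[SynthSpan(0, L, count)], L=L)
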