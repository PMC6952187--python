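"""Candidate-assembly enumeration by 5'→3' traversal over culled matches.

Matches starting within one target length of the origin seed chains that
extend strictly 3' match by match; gaps between consecutive matches are
budgeted as synthetic spans (small gaps ride inside primers). A chain
closes once it spans one full lap of the circle from its seed; closed
chains within the fragment-count limit become candidate assemblies with a
lower-bound cost estimate.
"""

from __future__ import annotations

import math
from decimal import Decimal
from typing import Iterable

from .config import DesignConfig, money, procurement_rate, synthetic_cost
from .model import CandidateAssembly, Match, OverLengthError, SynthSpan

# Nominal primer length used in pre-fill cost estimates; actual primers
# are priced at fill time.
NOMINAL_PRIMER_BP = 25
MIN_PRIMER_BP = 18


def select_seeds(matches: list[Match], L: int) -> list[Match]:
    """Matches whose start lies within one target length of the origin."""
    return [m for m in matches if m.query_start < L]


def estimate_synth_count(gap: int, config: DesignConfig) -> int:
    """Synthetic fragments needed for a coverage gap; small gaps are
    embedded in the flanking fragments' primers and cost none."""
    if gap < 0:
        raise ValueError(f"negative gap {gap}")
    if gap <= config.max_primer_fill_gap:
        return 0
    return math.ceil(gap / config.max_synthetic_length)


def traverse(matches: list[Match], L: int,
             config: DesignConfig) -> list[CandidateAssembly]:
    """Enumerate every closed, size-bounded candidate assembly.

    Rotation-equivalent chains (the same fragments reached from different
    seeds) are emitted once. An empty result means no repository coverage
    near the origin; the caller falls back to all-synthetic design.
    """
    ordered = sorted(matches, key=lambda m: (m.query_start, -m.query_end,
                                             m.repo, m.entry, m.subject_start))
    seeds = select_seeds(ordered, L)
    out: list[CandidateAssembly] = []
    seen: set[frozenset] = set()

    for seed in seeds:
        _extend([seed], seed.query_start + L, ordered, L, config, out, seen)
    return out


def _extend(chain: list[Match], close_at: int, ordered: list[Match], L: int,
            config: DesignConfig, out: list[CandidateAssembly],
            seen: set) -> None:
    head = chain[-1]
    # option 1: close the circle here (synthetic spans fill any remainder)
    candidate = _close(chain, close_at, L, config)
    if candidate is not None and candidate.fragment_count <= config.max_fragment_count:
        sig = candidate.signature()
        if sig not in seen:
            seen.add(sig)
            out.append(candidate)
    if len(chain) >= config.max_fragment_count:
        return
    # option 2: anneal a further match strictly 3' of the chain head
    for nxt in ordered:
        if nxt.query_start <= head.query_start:
            continue
        if nxt.query_start >= close_at:
            break  # beyond the closing point: cannot contribute to this lap
        if nxt.query_end <= head.query_end:
            continue  # engulfed within the head (possible across repos)
        gap = nxt.query_start - head.query_end
        if gap > 0 and estimate_synth_count(gap, config) + len(chain) + 1 \
                > config.max_fragment_count:
            continue
        _extend(chain + [nxt], close_at, ordered, L, config, out, seen)


def _close(chain: list[Match], close_at: int, L: int,
           config: DesignConfig) -> CandidateAssembly | None:
    """Build the candidate that closes the given chain at one full lap."""
    spans: list[SynthSpan] = []
    prev_end = None
    for m in chain:
        if prev_end is not None:
            gap = m.query_start - prev_end
            if gap > 0:
                count = estimate_synth_count(gap, config)
                if count:
                    spans.append(SynthSpan(prev_end, m.query_start, count))
                elif gap > config.max_primer_fill_gap:
                    return None
        prev_end = m.query_end
    closing_gap = close_at - chain[-1].query_end
    if closing_gap > 0:
        count = estimate_synth_count(closing_gap, config)
        if count:
            spans.append(SynthSpan(chain[-1].query_end, close_at, count))
        # a small closing gap rides in primers at the wrap junction
    cand = CandidateAssembly(matches=list(chain), synth_spans=spans, L=L)
    cand.estimated_cost = estimate_cost(cand, config, NOMINAL_PRIMER_BP)
    cand.lower_bound_cost = estimate_cost(cand, config, MIN_PRIMER_BP)
    return cand


def all_synthetic_candidate(L: int, config: DesignConfig) -> CandidateAssembly:
    """The pure-synthesis design: the whole circle as synthetic spans."""
    count = max(1, math.ceil(L / config.max_synthetic_length))
    cand = CandidateAssembly(
        matches=[], synth_spans=[SynthSpan(0, L, count)], L=L)
    cand.estimated_cost = estimate_cost(cand, config, NOMINAL_PRIMER_BP)
    cand.lower_bound_cost = cand.estimated_cost
    return cand


def estimate_cost(cand: CandidateAssembly, config: DesignConfig,
                  primer_bp: int) -> Decimal:
    """Pre-fill lower-bound estimate of a candidate's filled cost."""
    total = Decimal("0.00")
    for span in cand.synth_spans:
        per = math.ceil(span.length / span.fragment_count)
        for i in range(span.fragment_count):
            length = min(per, span.length - i * per)
            if length <= 0:
                continue
            try:
                total += synthetic_cost(length, config.synthetic_fragment_curve)
            except OverLengthError:
                total += synthetic_cost(config.max_synthetic_length,
                                        config.synthetic_fragment_curve)
    sources = {(m.repo, m.entry) for m in cand.matches}
    for repo, entry in sources:
        try:
            total += procurement_rate(repo, config)
        except Exception:
            pass  # unknown repo rates surface at fill time
    n_pcr = len(cand.matches)
    total += money(n_pcr * 2 * primer_bp * config.primer_cost_per_bp)
    total += money(n_pcr) * config.pcr_buffer_cost
    if n_pcr or cand.synth_spans:
        total += config.gibson_cost
    return money(total)
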