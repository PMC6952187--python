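"""Primer design for PCR build fragments.

Each PCR fragment amplifies a span of its source plasmid; junction
homology and small embedded gaps are added as 5' tails whose sequence
comes from the target plasmid. The binding region is grown from the
fragment end until its nearest-neighbor Tm reaches the acceptance window;
reported Tm covers the binding region only, never the tail.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import thermo
from ._seq import max_homopolymer_run
from .model import PlasmidPlanError, PrimerPair

MIN_BINDING = 18
MAX_BINDING = 30
MIN_TM = 57.0
MAX_TM = 72.0
MAX_HOMOPOLYMER = 8


class PrimerDesignError(PlasmidPlanError):
    """No acceptable binding region exists at a fragment end."""


def _binding_region(template_end: str, label: str) -> tuple[str, float]:
    """Choose a binding region reading 5'→3' from ``template_end[0:]``.

    Grows from MIN_BINDING until Tm >= MIN_TM; rejects ends whose best
    region stays outside [MIN_TM, MAX_TM] or is a near-homopolymer.
    """
    limit = min(MAX_BINDING, len(template_end))
    if limit < MIN_BINDING:
        raise PrimerDesignError(f"{label}: template shorter than {MIN_BINDING} bp")
    best = None
    for n in range(MIN_BINDING, limit + 1):
        region = template_end[:n]
        tm = thermo.binding_tm(region)
        best = (region, tm)
        if tm >= MIN_TM:
            break
    region, tm = best
    if tm < MIN_TM or tm > MAX_TM:
        raise PrimerDesignError(
            f"{label}: no binding region with Tm in [{MIN_TM}, {MAX_TM}] "
            f"(best {tm:.1f} °C over {len(region)} bp)")
    if max_homopolymer_run(region) > MAX_HOMOPOLYMER:
        raise PrimerDesignError(f"{label}: homopolymer run in binding region")
    return region, tm


def _best_end(template: str, slack: int, label: str
              ) -> tuple[int, str, float]:
    """Pick the binding start offset within an allowed flexibility range.

    Junctions with more than the minimum homology leave the primer a
    range on the source material; the shortest viable binding region wins
    (ties break toward the nominal fragment end). Returns
    (offset, region, tm).
    """
    best = None
    last_error: PrimerDesignError | None = None
    for delta in range(slack + 1):
        try:
            region, tm = _binding_region(template[delta:], label)
        except PrimerDesignError as exc:
            last_error = exc
            continue
        if best is None or len(region) < len(best[1]):
            best = (delta, region, tm)
            if len(region) == MIN_BINDING:
                break
    if best is None:
        raise last_error if last_error is not None else \
            PrimerDesignError(f"{label}: no viable binding region")
    return best


def design_primers(amplicon: str, added_left: int, added_right: int,
                   fragment_id: str = "fragment",
                   left_slack: int = 0, right_slack: int = 0) -> PrimerPair:
    """Design the primer pair for one PCR fragment.

    ``amplicon`` is the fragment's nominal target-strand sequence
    including junction tails; the first ``added_left`` and last
    ``added_right`` bp are tail sequence absent from the source template.
    ``left_slack``/``right_slack`` allow the binding site to slide into
    the amplicon (surplus junction homology); the chosen trims are
    reported on the returned pair and shrink the final fragment. A tail
    and slack never coexist on the same end.
    """
    from ._seq import revcomp

    core = amplicon[added_left:len(amplicon) - added_right or None]
    budget = len(core) - 2 * MIN_BINDING - 4
    if budget < 0:
        raise PrimerDesignError(f"{fragment_id}: amplifiable core too short")
    left_slack = min(left_slack, budget)
    right_slack = min(right_slack, max(0, budget - left_slack))
    dl, fwd_bind, fwd_tm = _best_end(core, left_slack, f"{fragment_id} fwd")
    dr, rev_bind, rev_tm = _best_end(revcomp(core), right_slack,
                                     f"{fragment_id} rev")
    fwd = amplicon[:added_left] + fwd_bind
    rev = revcomp(amplicon[len(amplicon) - added_right:]) + rev_bind if added_right \
        else rev_bind
    return PrimerPair(
        fwd=fwd, rev=rev, fwd_tm=fwd_tm, rev_tm=rev_tm,
        fwd_binding_len=len(fwd_bind), rev_binding_len=len(rev_bind),
        added_left=added_left, added_right=added_right,
        trim_left=dl, trim_right=dr,
    )
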