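"""Domain types shared across the design pipeline.

Coordinate conventions
----------------------
The circular target of length ``L`` is searched as its doubled sequence, so
match coordinates live on ``[0, 2L)``; a candidate assembly occupies one lap
``[seed_start, seed_start + L)`` of that axis. Spans are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional


class PlasmidPlanError(Exception):
    """Base class for all package errors."""


class ConfigError(PlasmidPlanError):
    pass


class OverLengthError(ConfigError):
    """A span is longer than the largest synthesis cost-curve tier."""


class InputError(PlasmidPlanError):
    pass


class SearchError(PlasmidPlanError):
    """External alignment-engine invocation failed."""


@dataclass(frozen=True)
class Match:
    """A repository hit on the doubled target coordinate axis."""

    repo: str
    entry: str
    query_start: int        # on [0, 2L)
    query_end: int
    subject_start: int      # on the source entry, forward-strand coords
    subject_end: int
    strand: str             # '+' or '-'
    identity: float         # percent, (0, 100]

    def __post_init__(self) -> None:
        if not self.query_start < self.query_end:
            raise ValueError(f"empty match span [{self.query_start}, {self.query_end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.query_end - self.query_start

    def key(self) -> tuple:
        return (self.repo, self.entry, self.subject_start, self.subject_end,
                self.strand, self.query_start)


@dataclass(frozen=True)
class ScoringParams:
    """blastn-style alignment scoring for a requested percent identity."""

    reward: int
    penalty: int
    gap_open: int
    gap_extend: int
    evalue_cutoff: float = 10.0


@dataclass
class SynthSpan:
    """A gap in repository coverage to be closed with synthetic DNA."""

    gap_start: int
    gap_end: int
    fragment_count: int

    @property
    def length(self) -> int:
        return self.gap_end - self.gap_start


@dataclass
class CandidateAssembly:
    """An ordered chain of matches plus estimated synthetic spans, pre-fill."""

    matches: list[Match]
    synth_spans: list[SynthSpan]
    L: int
    estimated_cost: Decimal = Decimal("0.00")
    lower_bound_cost: Decimal = Decimal("0.00")

    @property
    def fragment_count(self) -> int:
        return len(self.matches) + sum(s.fragment_count for s in self.synth_spans)

    @property
    def seed_start(self) -> int:
        return self.matches[0].query_start if self.matches else 0

    def signature(self) -> frozenset:
        """Rotation-invariant identity of the chain (match spans mod L)."""
        parts = [("m", m.repo, m.entry, m.subject_start, m.subject_end,
                  m.strand, m.query_start % self.L) for m in self.matches]
        parts += [("s", s.gap_start % self.L, s.gap_end - s.gap_start)
                  for s in self.synth_spans]
        return frozenset(parts)


@dataclass
class PrimerPair:
    """Amplification primers for one PCR fragment, 5'→3'."""

    fwd: str
    rev: str
    fwd_tm: float
    rev_tm: float
    fwd_binding_len: int
    rev_binding_len: int
    # target-axis bp added as 5' tails (junction homology + embedded gap)
    added_left: int = 0
    added_right: int = 0
    # bp trimmed off the nominal span by flexible-range primer placement
    trim_left: int = 0
    trim_right: int = 0


@dataclass
class BuildFragment:
    """One concrete output fragment of a filled design."""

    id: str
    kind: str                         # 'pcr' | 'synthetic' | 'existing'
    sequence: str                     # final, target-strand
    start: int                        # final span on the target axis
    end: int
    repo: Optional[str] = None
    entry: Optional[str] = None
    subject_start: Optional[int] = None
    subject_end: Optional[int] = None
    strand: Optional[str] = None
    primers: Optional[PrimerPair] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CostItem:
    category: str                     # synthesis|primers|procurement|pcr_reagents|gibson|human
    description: str
    amount: Decimal


@dataclass
class CostBreakdown:
    items: list[CostItem] = field(default_factory=list)

    @property
    def total(self) -> Decimal:
        return sum((i.amount for i in self.items), Decimal("0.00"))

    def add(self, category: str, description: str, amount: Decimal) -> None:
        self.items.append(CostItem(category, description, amount))


@dataclass
class Solution:
    """A filled assembly: ordered fragments, primers, and itemized cost."""

    fragments: list[BuildFragment]
    cost: CostBreakdown

    @property
    def total(self) -> Decimal:
        return self.cost.total

    @property
    def fragment_count(self) -> int:
        return len(self.fragments)


@dataclass
class FillFailure:
    """Typed reason a candidate could not be filled (a value, not an error)."""

    reason: str                       # 'primer' | 'ectopic' | 'hairpin' | 'junction'
    detail: str
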