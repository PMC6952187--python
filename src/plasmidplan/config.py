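"""Design configuration and every monetary computation.

All money is exact decimal, quantized to cents, so totals are reproducible.
Synthesis pricing is a tiered curve: the first integer length-threshold at
or above the fragment length selects the tier; a fixed tier costs its
amount outright, a per-bp tier costs length × rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from .model import (
    BuildFragment,
    ConfigError,
    CostBreakdown,
    OverLengthError,
    Solution,
)

log = logging.getLogger(__name__)

CENT = Decimal("0.01")


def money(x) -> Decimal:
    """Convert to an exact 2-dp decimal amount."""
    return Decimal(str(x)).quantize(CENT, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class CostTier:
    threshold: int          # max length (bp) this tier covers
    cost: Decimal
    per_bp: bool


@dataclass(frozen=True)
class CostCurve:
    """Tiered synthesis price curve, thresholds strictly increasing."""

    tiers: tuple[CostTier, ...]

    def __post_init__(self) -> None:
        if not self.tiers:
            raise ConfigError("cost curve needs at least one tier")
        thresholds = [t.threshold for t in self.tiers]
        if thresholds != sorted(set(thresholds)):
            raise ConfigError(f"cost-curve thresholds must strictly increase: {thresholds}")
        for t in self.tiers:
            if t.cost < 0:
                raise ConfigError(f"negative cost in tier {t.threshold}")

    @property
    def max_length(self) -> int:
        return self.tiers[-1].threshold

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CostCurve":
        """Build from a YAML-style ``{length: {cost, fixed}}`` map."""
        tiers = []
        for threshold in sorted(int(k) for k in mapping):
            entry = mapping[threshold] if threshold in mapping else mapping[str(threshold)]
            cost = money(entry["cost"])
            fixed = bool(entry.get("fixed", True))
            tiers.append(CostTier(threshold, cost, per_bp=not fixed))
        return cls(tuple(tiers))


# Default fragment curve: gBlocks-style tiers; gene curve: flat per-bp in a
# pre-cloned vector. Both are placeholders for the user's provider prices.
DEFAULT_FRAGMENT_CURVE = CostCurve((
    CostTier(250, money(89), False),
    CostTier(500, money(89), False),
    CostTier(750, money(149), False),
    CostTier(1000, money(179), False),
    CostTier(1500, money(269), False),
    CostTier(2000, money(349), False),
    CostTier(3000, money("0.20"), True),
))

DEFAULT_GENE_CURVE = CostCurve((
    CostTier(3000, money("0.89"), True),
))

DEFAULT_PROCUREMENT = {"igem": money(0), "addgene": money(65), "dnasu": money(55)}


@dataclass
class DesignConfig:
    synthetic_fragment_curve: CostCurve = DEFAULT_FRAGMENT_CURVE
    synthetic_gene_curve: CostCurve = DEFAULT_GENE_CURVE
    primer_cost_per_bp: Decimal = money("0.60")
    pcr_buffer_cost: Decimal = money("0.27")
    gibson_cost: Decimal = money("12.98")
    procurement_cost: dict[str, Decimal] = field(
        default_factory=lambda: dict(DEFAULT_PROCUREMENT))
    human_cost_pcr: Decimal = money(0)
    human_cost_gibson: Decimal = money(0)
    min_homology: int = 15
    max_homology: int = 150
    max_primer_fill_gap: int = 20
    max_fragment_count: int = 6
    max_ectopic_tm: float = 45.0
    max_hairpin_tm: float = 47.0
    min_synthetic_length: int = 125
    max_synthetic_length: int = 0       # 0 → largest curve threshold
    default_identity_sequence: float = 98.0
    default_identity_feature: float = 96.0

    def __post_init__(self) -> None:
        if self.max_synthetic_length <= 0:
            self.max_synthetic_length = self.synthetic_fragment_curve.max_length
        self.validate()

    def validate(self) -> None:
        if self.min_homology > self.max_homology:
            raise ConfigError(
                f"min_homology ({self.min_homology}) > max_homology ({self.max_homology})")
        if self.max_fragment_count < 1:
            raise ConfigError("max_fragment_count must be >= 1")
        for name in ("primer_cost_per_bp", "pcr_buffer_cost", "gibson_cost",
                     "human_cost_pcr", "human_cost_gibson"):
            if getattr(self, name) < 0:
                raise ConfigError(f"negative cost: {name}")
        for repo, cost in self.procurement_cost.items():
            if cost < 0:
                raise ConfigError(f"negative procurement cost for {repo}")
        if self.max_primer_fill_gap < 0:
            raise ConfigError("max_primer_fill_gap must be >= 0")
        if self.min_synthetic_length < 1:
            raise ConfigError("min_synthetic_length must be >= 1")

    def with_procurement(self, extra: Mapping[str, Decimal]) -> "DesignConfig":
        merged = dict(self.procurement_cost)
        merged.update({k.lower(): money(v) for k, v in extra.items()})
        return replace(self, procurement_cost=merged)


# YAML key → (attribute, converter). Kebab-case mirrors the config file
# dialect; the two screening thresholds keep their historical long names.
_KEYS = {
    "primer-cost-per-bp": ("primer_cost_per_bp", money),
    "pcr-buffer-cost": ("pcr_buffer_cost", money),
    "gibson-cost": ("gibson_cost", money),
    "human-cost-pcr": ("human_cost_pcr", money),
    "human-cost-gibson": ("human_cost_gibson", money),
    "min-homology": ("min_homology", int),
    "max-homology": ("max_homology", int),
    "max-primer-fill-gap": ("max_primer_fill_gap", int),
    "max-fragment-count": ("max_fragment_count", int),
    "pcr-primer-max-ectopic-tm": ("max_ectopic_tm", float),
    "fragments-max-hairpin-tm": ("max_hairpin_tm", float),
    "min-synthetic-length": ("min_synthetic_length", int),
    "max-synthetic-length": ("max_synthetic_length", int),
    "default-identity-sequence": ("default_identity_sequence", float),
    "default-identity-feature": ("default_identity_feature", float),
}


def load_config(path) -> DesignConfig:
    """Parse a YAML configuration file; absent keys take package defaults.

    Unknown keys warn and are ignored; malformed values raise
    :class:`ConfigError` naming the offending key.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a map, got {type(data).__name__}")

    kwargs: dict = {}
    for key, value in data.items():
        norm = str(key).strip().lower()
        if norm in ("synthetic-fragment-cost", "synthetic_fragment_curve"):
            kwargs["synthetic_fragment_curve"] = _parse_curve(norm, value)
        elif norm in ("synthetic-gene-cost", "synthetic_gene_curve"):
            kwargs["synthetic_gene_curve"] = _parse_curve(norm, value)
        elif norm in ("procurement-cost", "procurement_cost"):
            if not isinstance(value, dict):
                raise ConfigError(f"{key}: expected a map of repository → cost")
            kwargs["procurement_cost"] = {
                str(r).lower(): _money_key(key, c) for r, c in value.items()}
        elif norm in _KEYS:
            attr, conv = _KEYS[norm]
            try:
                kwargs[attr] = conv(value)
            except (ValueError, ArithmeticError) as exc:
                raise ConfigError(f"bad value for key {key!r}: {value!r}") from exc
        elif norm.replace("-", "_") in DesignConfig.__dataclass_fields__:
            attr = norm.replace("-", "_")
            f = DesignConfig.__dataclass_fields__[attr]
            conv = money if f.type == "Decimal" else (
                float if "float" in str(f.type) else int)
            kwargs[attr] = conv(value)
        else:
            warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)

    for attr in ("primer_cost_per_bp", "pcr_buffer_cost", "gibson_cost",
                 "human_cost_pcr", "human_cost_gibson"):
        if attr in kwargs and kwargs[attr] < 0:
            raise ConfigError(f"negative cost for {attr}")
    if "procurement_cost" in kwargs:
        merged = dict(DEFAULT_PROCUREMENT)
        merged.update(kwargs["procurement_cost"])
        kwargs["procurement_cost"] = merged
    return DesignConfig(**kwargs)


def _money_key(key, value) -> Decimal:
    try:
        amount = money(value)
    except ArithmeticError as exc:
        raise ConfigError(f"bad cost under {key!r}: {value!r}") from exc
    if amount < 0:
        raise ConfigError(f"negative cost under {key!r}: {value!r}")
    return amount


def _parse_curve(key, value) -> CostCurve:
    if not isinstance(value, dict):
        raise ConfigError(f"{key}: expected a map of length → {{cost, fixed}}")
    try:
        return CostCurve.from_mapping(value)
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"{key}: malformed cost curve: {exc}") from exc


def synthetic_cost(length: int, curve: CostCurve) -> Decimal:
    """Price one synthetic span off the tiered curve.

    The first tier whose threshold is at or above ``length`` applies;
    lengths beyond the last tier raise :class:`OverLengthError` — the caller
    must split the span first.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    for tier in curve.tiers:
        if tier.threshold >= length:
            if tier.per_bp:
                return money(tier.cost * length)
            return tier.cost
    raise OverLengthError(
        f"{length} bp exceeds the largest curve threshold ({curve.max_length} bp)")


def primer_pair_cost(fwd_len: int, rev_len: int, config: DesignConfig) -> Decimal:
    if fwd_len < 1 or rev_len < 1:
        raise ValueError("primer lengths must be >= 1")
    return money((fwd_len + rev_len) * config.primer_cost_per_bp)


def procurement_rate(repo: str, config: DesignConfig) -> Decimal:
    rate = config.procurement_cost.get(repo.lower())
    if rate is None:
        raise ConfigError(f"no procurement cost configured for repository {repo!r}")
    return rate


def assembly_cost(solution: Solution, config: DesignConfig) -> CostBreakdown:
    """Itemized cost of a fully filled solution.

    One procurement charge per distinct (repository, entry) source plasmid;
    PCR buffer per PCR fragment; Gibson master mix once per assembly; no
    Gibson or PCR charges for an existing whole-plasmid solution.
    """
    bd = CostBreakdown()
    pcr_frags = [f for f in solution.fragments if f.kind == "pcr"]
    synth_frags = [f for f in solution.fragments if f.kind == "synthetic"]
    existing = [f for f in solution.fragments if f.kind == "existing"]

    for frag in sorted(pcr_frags, key=lambda f: f.id):
        if frag.primers is None:
            raise ValueError(f"PCR fragment {frag.id} has no primers")
        p = frag.primers
        bd.add("primers", f"primers for {frag.id} ({len(p.fwd)}+{len(p.rev)} bp)",
               primer_pair_cost(len(p.fwd), len(p.rev), config))
    for frag in sorted(synth_frags, key=lambda f: f.id):
        bd.add("synthesis", f"synthetic fragment {frag.id} ({frag.length} bp)",
               synthetic_cost(frag.length, config.synthetic_fragment_curve))

    seen: set[tuple[str, str]] = set()
    for frag in sorted(pcr_frags + existing, key=lambda f: f.id):
        src = (frag.repo or "", frag.entry or "")
        if src in seen or frag.repo is None:
            continue
        seen.add(src)
        rate = procurement_rate(frag.repo, config)
        if rate > 0:
            bd.add("procurement", f"source plasmid {frag.entry} ({frag.repo})", rate)

    for frag in sorted(pcr_frags, key=lambda f: f.id):
        if config.pcr_buffer_cost > 0:
            bd.add("pcr_reagents", f"PCR buffer for {frag.id}", config.pcr_buffer_cost)

    assembled = bool(pcr_frags or synth_frags or len(solution.fragments) > 1)
    if assembled and config.gibson_cost > 0:
        bd.add("gibson", "Gibson assembly master mix", config.gibson_cost)
    if pcr_frags and config.human_cost_pcr > 0:
        bd.add("human", "PCR bench time", config.human_cost_pcr)
    if assembled and config.human_cost_gibson > 0:
        bd.add("human", "Gibson bench time", config.human_cost_gibson)
    return bd
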