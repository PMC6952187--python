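"""End-to-end plasmid design: sequence, feature, and fragment modes.

The design flow is: canonicalize the circular target (smallest rotation
first, so equivalent inputs give identical output), search the selected
repositories with the doubled query, cull engulfed matches, traverse to
candidate assemblies, fill in ascending estimated-cost order, and keep
the Pareto front. When repositories offer nothing, the all-synthetic
design is the answer; it is always in the candidate pool regardless, so
reuse must beat synthesis to be reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Optional

from ._seq import canonical_rotation, is_iupac_dna, revcomp
from .config import DesignConfig
from .filling import fill_candidates, pareto_front
from .model import FillFailure, InputError, Match, Solution
from .repositories import (
    EnzymeDB,
    FeatureDB,
    LinearFragment,
    Repository,
    anneal_to_backbone,
    digest_backbone,
    lookup_feature,
)
from .search import cull_engulfed, find_matches
from .traversal import all_synthetic_candidate, traverse

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class DesignRequest:
    mode: str                               # 'sequence' | 'features' | 'fragments'
    sequence: Optional[str] = None
    features: list[str] = field(default_factory=list)
    fragments: list[str] = field(default_factory=list)
    repos: list[Repository] = field(default_factory=list)
    feature_db: Optional[FeatureDB] = None
    enzyme_db: Optional[EnzymeDB] = None
    backbone: Optional[str] = None          # raw sequence or "repo:entry"
    enzyme: Optional[str] = None
    identity: Optional[float] = None
    config: DesignConfig = field(default_factory=DesignConfig)
    backend: str = "blast"

    def __post_init__(self) -> None:
        if self.mode not in ("sequence", "features", "fragments"):
            raise InputError(f"unknown design mode {self.mode!r}")
        if (self.backbone is None) != (self.enzyme is None):
            raise InputError("backbone and enzyme must be given together")
        if self.mode == "features" and not self.features:
            raise InputError("feature mode needs at least one feature name")


@dataclass
class DesignResult:
    target: str
    mode: str
    identity: float
    solutions: list[Solution]
    failures: list[FillFailure]
    diagnostics: list[str]
    config: DesignConfig

    @property
    def cheapest(self) -> Optional[Solution]:
        return self.solutions[0] if self.solutions else None

    def to_payload(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "mode": self.mode,
            "identity": self.identity,
            "target_length": len(self.target),
            "target_sequence": self.target,
            "diagnostics": list(self.diagnostics),
            "failures": [{"reason": f.reason, "detail": f.detail}
                         for f in self.failures],
            "solutions": [_solution_payload(s) for s in self.solutions],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_payload(), sort_keys=True, indent=2) + "\n"


def _solution_payload(sol: Solution) -> dict:
    frags = []
    for f in sol.fragments:
        entry = {
            "id": f.id,
            "kind": f.kind,
            "length": f.length,
            "sequence": f.sequence,
            "start": f.start,
            "end": f.end,
        }
        if f.repo is not None:
            entry["repository"] = f.repo
            entry["entry"] = f.entry
            entry["subject_span"] = [f.subject_start, f.subject_end]
            entry["strand"] = f.strand
        if f.primers is not None:
            entry["primers"] = {
                "fwd": f.primers.fwd,
                "rev": f.primers.rev,
                "fwd_tm": round(f.primers.fwd_tm, 2),
                "rev_tm": round(f.primers.rev_tm, 2),
            }
        frags.append(entry)
    return {
        "fragment_count": sol.fragment_count,
        "fragments": frags,
        "cost": {
            "total": str(sol.total),
            "items": [{"category": i.category, "description": i.description,
                       "amount": str(i.amount)} for i in sol.cost.items],
        },
    }


def make_sequence(request: DesignRequest) -> DesignResult:
    """Design a circular target given directly as a sequence."""
    seq = (request.sequence or "").upper().replace("\n", "").replace(" ", "")
    if not is_iupac_dna(seq):
        raise InputError("target sequence is empty or has non-IUPAC characters")
    config = request.config
    if len(seq) < 2 * config.min_homology:
        raise InputError(f"target too short ({len(seq)} bp)")
    target = canonical_rotation(seq)
    identity = request.identity if request.identity is not None \
        else config.default_identity_sequence
    return _design(target, request, identity)


def make_features(request: DesignRequest) -> DesignResult:
    """Design from an ordered feature-name list; a leading '!' reverses a
    feature's orientation. With a backbone and enzyme, the backbone is
    digested, its largest fragment kept, and the insert annealed to it."""
    db = request.feature_db
    if db is None:
        raise InputError("feature mode needs a feature database")
    parts = []
    misses = []
    for raw in request.features:
        name = raw.strip()
        flip = name.startswith("!")
        if flip:
            name = name[1:]
        hit = lookup_feature(name, db)
        if not hit.found:
            hint = f" (did you mean {', '.join(hit.suggestions)}?)" \
                if hit.suggestions else ""
            misses.append(f"{name}{hint}")
            continue
        parts.append(revcomp(hit.sequence) if flip else hit.sequence)
    if misses:
        raise InputError("unknown feature name(s): " + "; ".join(misses))
    insert = "".join(parts)
    target = insert
    if request.backbone is not None:
        backbone_seq = _resolve_backbone(request)
        enzyme = (request.enzyme_db or None) and request.enzyme_db.get(request.enzyme)
        if enzyme is None:
            raise InputError(f"enzyme {request.enzyme!r} not in the enzyme database")
        linear = digest_backbone(backbone_seq, enzyme, circular=True)
        target = anneal_to_backbone(insert, linear)
    identity = request.identity if request.identity is not None \
        else request.config.default_identity_feature
    sub = DesignRequest(
        mode="sequence", sequence=target, repos=request.repos,
        identity=identity, config=request.config, backend=request.backend)
    return make_sequence(sub)


def make_fragments(request: DesignRequest) -> DesignResult:
    """Plan junctions and primers for user-supplied fragments in order;
    no repository search is performed."""
    frags = [f.upper() for f in request.fragments]
    if not frags or any(not is_iupac_dna(f) for f in frags):
        raise InputError("fragment mode needs non-empty IUPAC fragments")
    config = request.config
    target_parts = []
    starts = []
    pos = 0
    for i, frag in enumerate(frags):
        if i == 0:
            starts.append(0)
            target_parts.append(frag)
            pos = len(frag)
            continue
        prev = target_parts[-1]
        o = _max_overlap(prev, frag, config.max_homology)
        starts.append(pos - o)
        target_parts.append(frag[o:])
        pos += len(frag) - o
    target = "".join(target_parts)
    closing = _max_overlap(frags[-1], frags[0], config.max_homology)
    if closing:
        target = target[:len(target) - closing]
    L = len(target)

    records = {f"fragment{i + 1}": frag for i, frag in enumerate(frags)}
    from .repositories import RepoRecord
    user = Repository(name="user", records={
        k: RepoRecord(k, v) for k, v in records.items()})
    config = config.with_procurement({"user": Decimal("0")})
    matches = []
    for i, frag in enumerate(frags):
        start = starts[i]
        end = min(start + len(frag), start + L)
        matches.append(Match("user", f"fragment{i + 1}", start, end,
                             0, end - start, "+", 100.0))
    from .model import CandidateAssembly
    cand = CandidateAssembly(matches=matches, synth_spans=[], L=L)
    solutions, failures = fill_candidates(
        [cand], target, config, {"user": user})
    return DesignResult(target=target, mode="fragments", identity=100.0,
                        solutions=solutions, failures=failures,
                        diagnostics=[], config=config)


def _max_overlap(left: str, right: str, cap: int) -> int:
    for o in range(min(cap, len(left), len(right)), 0, -1):
        if left[-o:] == right[:o]:
            return o
    return 0


def _resolve_backbone(request: DesignRequest) -> str:
    ref = request.backbone
    if is_iupac_dna(ref):
        return ref.upper()
    if ":" in ref:
        repo_name, entry = ref.split(":", 1)
        for repo in request.repos:
            if repo.name == repo_name and entry in repo.records:
                return repo.records[entry].sequence
    for repo in request.repos:
        if ref in repo.records:
            return repo.records[ref].sequence
    raise InputError(f"backbone {ref!r} not found in the selected repositories")


def _design(target: str, request: DesignRequest, identity: float) -> DesignResult:
    config = request.config
    extra = {r.name: r.procurement_cost for r in request.repos
             if r.procurement_cost is not None}
    for r in request.repos:
        if r.procurement_cost is None and r.name.lower() not in config.procurement_cost:
            extra[r.name] = Decimal("0")   # user databases procure for free
    if extra:
        config = config.with_procurement(extra)

    diagnostics: list[str] = []
    matches: list[Match] = []
    if request.repos:
        matches = cull_engulfed(find_matches(
            target, request.repos, identity, backend=request.backend))
    candidates = traverse(matches, len(target), config)
    if not candidates:
        diagnostics.append("no repository coverage near origin; "
                           "falling back to synthesis")
    candidates.append(all_synthetic_candidate(len(target), config))
    repo_map = {r.name: r for r in request.repos}
    solutions, failures = fill_candidates(candidates, target, config, repo_map)
    solutions.sort(key=lambda s: (s.total, s.fragment_count))
    return DesignResult(target=target, mode=request.mode, identity=identity,
                        solutions=solutions, failures=failures,
                        diagnostics=diagnostics, config=config)


def design(request: DesignRequest) -> DesignResult:
    if request.mode == "sequence":
        return make_sequence(request)
    if request.mode == "features":
        return make_features(request)
    return make_fragments(request)


# --------------------------------------------------------------------------
# output writers


def write_result(result: DesignResult, json_path,
                 fasta_path=None, genbank_path=None) -> None:
    """Write the JSON payload and optional FASTA / GenBank companions."""
    Path(json_path).write_text(result.to_json())
    if fasta_path is not None:
        _write_fasta(result, fasta_path)
    if genbank_path is not None:
        _write_genbank(result, genbank_path)


def _write_fasta(result: DesignResult, path) -> None:
    lines = []
    for si, sol in enumerate(result.solutions, 1):
        for frag in sol.fragments:
            lines.append(f">solution{si}_{frag.id} {frag.kind}")
            lines.append(frag.sequence)
            if frag.primers is not None:
                lines.append(f">solution{si}_{frag.id}_fwd primer")
                lines.append(frag.primers.fwd)
                lines.append(f">solution{si}_{frag.id}_rev primer")
                lines.append(frag.primers.rev)
    Path(path).write_text("\n".join(lines) + "\n")


def _write_genbank(result: DesignResult, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    L = len(result.target)
    record = SeqRecord(Seq(result.target), id="target", name="target",
                       description="designed circular target")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    sol = result.cheapest
    if sol is not None:
        for frag in sol.fragments:
            if frag.length >= L:
                record.features.append(SeqFeature(
                    FeatureLocation(0, L), type="misc_feature",
                    qualifiers={"label": [f"{frag.id} ({frag.kind})"]}))
                continue
            s, e = frag.start % L, frag.end % L if frag.end % L else L
            if s < e:
                loc = FeatureLocation(s, e)
            else:
                from Bio.SeqFeature import CompoundLocation
                loc = CompoundLocation([FeatureLocation(s, L),
                                        FeatureLocation(0, e)])
            record.features.append(SeqFeature(
                loc, type="misc_feature",
                qualifiers={"label": [f"{frag.id} ({frag.kind})"]}))
    from Bio import SeqIO
    SeqIO.write([record], str(path), "genbank")
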