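"""Fragment search: find repository material covering the circular target.

The target sequence is doubled end-to-end and queried against each
repository so hits spanning the circular origin appear as ordinary
intervals on ``[0, 2L)``. Alignment scoring depends on the requested
percent identity; matches fully engulfed by others are culled.

Two backends: ``blast`` shells out to blastn/makeblastdb (the production
path), ``kmer`` is an in-process seed-and-extend exact matcher used where
external processes are too slow or unavailable.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from pathlib import Path
from typing import Iterable

from ._seq import revcomp
from .model import Match, ScoringParams, SearchError
from .repositories import Repository

log = logging.getLogger(__name__)

# identity → (reward, penalty, gap_open, gap_extend); nearest row at or
# below the requested identity applies. Rows follow the alignment engine
# manual's reward/penalty guidance; identities above 99 switch to strict
# penalties so imperfect hits and frayed fragment ends are rejected.
_SCORING_ROWS = [
    (50, ScoringParams(1, -1, 2, 1)),
    (90, ScoringParams(1, -2, 1, 2)),
    (95, ScoringParams(2, -3, 4, 2)),
]
_STRICT = ScoringParams(1, -6, 6, 6)


def scoring_params(identity: float) -> ScoringParams:
    """Alignment scoring for a requested percent identity in [50, 100]."""
    if not 50 <= identity <= 100:
        raise ValueError(f"identity must be in [50, 100], got {identity}")
    if identity > 99:
        return _STRICT
    row = _SCORING_ROWS[0][1]
    for threshold, params in _SCORING_ROWS:
        if threshold <= identity:
            row = params
    return row


def find_matches(target: str, repos: Iterable[Repository], identity: float,
                 backend: str = "blast", min_length: int = 18) -> list[Match]:
    """Query the doubled target against each repository.

    Returns matches with identity >= the request, on doubled coordinates,
    sorted by (query_start, descending length); hits longer than L are
    truncated to L.
    """
    L = len(target)
    if L < min_length:
        raise ValueError(f"target too short to search ({L} bp)")
    doubled = target + target
    params = scoring_params(identity)
    matches: list[Match] = []
    for repo in repos:
        if backend == "blast":
            hits = _blast_hits(doubled, repo, params, identity)
        elif backend == "kmer":
            hits = _kmer_hits(doubled, repo, min_length)
        else:
            raise ValueError(f"unknown search backend {backend!r}")
        for m in hits:
            if m.identity + 1e-9 < identity or m.length < min_length:
                continue
            if m.length > L:
                m = Match(m.repo, m.entry, m.query_start, m.query_start + L,
                          m.subject_start, m.subject_end, m.strand, m.identity)
            matches.append(m)
    matches.sort(key=lambda m: (m.query_start, -m.length, m.repo, m.entry,
                                m.subject_start, m.strand))
    return matches


def cull_engulfed(matches: list[Match]) -> list[Match]:
    """Drop matches whose query span is properly contained in another's;
    equal spans keep the lexicographically first (repo, entry)."""
    spans: dict[tuple[int, int], Match] = {}
    for m in matches:
        key = (m.query_start, m.query_end)
        old = spans.get(key)
        if old is None or (m.repo, m.entry) < (old.repo, old.entry):
            spans[key] = m
    kept = []
    unique = sorted(spans.values(), key=lambda m: (m.query_start, -m.query_end))
    max_end = -1
    for m in unique:
        if m.query_end <= max_end:
            continue  # properly contained in an earlier, wider span
        kept.append(m)
        max_end = m.query_end
    kept.sort(key=lambda m: (m.query_start, -m.query_end))
    return kept


# --------------------------------------------------------------------------
# BLAST backend


def _blast_hits(doubled: str, repo: Repository, params: ScoringParams,
                identity: float) -> list[Match]:
    db = repo.blast_db()
    visible = {r.id for r in repo.visible_records()}
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        fh.write(">query\n")
        fh.write(doubled)
        fh.write("\n")
        query_path = fh.name
    cmd = [
        "blastn", "-task", "blastn",
        "-query", query_path, "-db", str(db),
        "-reward", str(params.reward), "-penalty", str(params.penalty),
        "-gapopen", str(params.gap_open), "-gapextend", str(params.gap_extend),
        "-evalue", str(params.evalue_cutoff),
        "-perc_identity", str(identity),
        "-num_threads", "1", "-dust", "no", "-soft_masking", "false",
        "-outfmt", "6 sseqid qstart qend sstart send pident length sstrand",
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    Path(query_path).unlink(missing_ok=True)
    if proc.returncode != 0:
        raise SearchError(f"blastn failed for {repo.name}: {proc.stderr.strip()}")
    hits = []
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        sid, qs, qe, ss, se, pid, _length, sstrand = f
        if sid not in visible:
            continue
        qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
        if sstrand == "minus" or ss > se:
            strand = "-"
            ss, se = min(ss, se), max(ss, se)
        else:
            strand = "+"
        hits.append(Match(repo.name, sid, qs - 1, qe, ss - 1, se, strand,
                          float(pid)))
    return hits


# --------------------------------------------------------------------------
# In-process exact seed-and-extend backend


def _kmer_hits(doubled: str, repo: Repository, min_length: int,
               k: int = 12) -> list[Match]:
    """Maximal exact matches (both strands) between the doubled query and
    each visible record, reported at 100% identity."""
    hits: list[Match] = []
    for rec in repo.visible_records():
        hits.extend(_exact_matches(doubled, rec.sequence, repo.name, rec.id,
                                   "+", min_length, k))
        n = len(rec.sequence)
        for m in _exact_matches(doubled, revcomp(rec.sequence), repo.name,
                                rec.id, "-", min_length, k):
            # map subject coords back to the forward strand of the record
            hits.append(Match(m.repo, m.entry, m.query_start, m.query_end,
                              n - m.subject_end, n - m.subject_start, "-",
                              m.identity))
    # deduplicate (a maximal match can be seeded many times)
    seen = set()
    out = []
    for m in hits:
        key = m.key()
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def _exact_matches(query: str, subject: str, repo: str, entry: str,
                   strand: str, min_length: int, k: int) -> list[Match]:
    if len(subject) < k or len(query) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        index.setdefault(subject[i:i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()
    matches = []
    qlen, slen = len(query), len(subject)
    pos = 0
    while pos <= qlen - k:
        seed = query[pos:pos + k]
        for spos in index.get(seed, ()):  # extend each seed maximally
            qi, si = pos, spos
            while qi > 0 and si > 0 and query[qi - 1] == subject[si - 1]:
                qi -= 1
                si -= 1
            qj, sj = pos + k, spos + k
            while qj < qlen and sj < slen and query[qj] == subject[sj]:
                qj += 1
                sj += 1
            if qj - qi >= min_length:
                key = (qi, si, qj - qi)
                if key not in found:
                    found.add(key)
                    if strand == "+":
                        matches.append(Match(repo, entry, qi, qj, si, sj,
                                             "+", 100.0))
                    else:
                        matches.append(Match(repo, entry, qi, qj, si, sj,
                                             "-", 100.0))
        pos += 1
    return matches
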