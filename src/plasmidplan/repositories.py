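"""Fragment repositories and the feature / enzyme databases.

A repository is a named multi-FASTA of source plasmids made searchable
(BLAST database built lazily on first use; the in-process backend needs
no index). The feature database maps names to sequences, the enzyme
database maps names to recognition sites in caret notation
(e.g. ``CTGCA^G``); both are 2-column TSV, '#' comments skipped.
"""

from __future__ import annotations

import difflib
import logging
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from ._seq import IUPAC_DNA, iupac_pattern, revcomp
from .model import InputError, PlasmidPlanError

log = logging.getLogger(__name__)


@dataclass
class RepoRecord:
    id: str
    sequence: str
    circular: bool = False
    header: str = ""

    @property
    def tokens(self) -> list[str]:
        return self.header.split()


@dataclass
class Repository:
    """A named, searchable collection of source plasmid sequences."""

    name: str
    records: dict[str, RepoRecord]
    procurement_cost: Optional[Decimal] = None
    fasta_path: Optional[Path] = None
    _excluded: frozenset = frozenset()
    _blast_db: Optional[Path] = None

    def visible_records(self) -> list[RepoRecord]:
        return [r for r in self.records.values() if r.id not in self._excluded]

    def blast_db(self) -> Path:
        """Path prefix of the BLAST nucleotide database, built on demand."""
        if self._blast_db is None:
            workdir = Path(tempfile.mkdtemp(prefix=f"ppdb_{self.name}_"))
            fasta = workdir / f"{self.name}.fa"
            with fasta.open("w") as fh:
                for rec in self.records.values():
                    fh.write(f">{rec.id}\n{rec.sequence}\n")
            proc = subprocess.run(
                ["makeblastdb", "-in", str(fasta), "-dbtype", "nucl",
                 "-out", str(workdir / self.name)],
                capture_output=True, text=True)
            if proc.returncode != 0:
                raise PlasmidPlanError(
                    f"makeblastdb failed for {self.name}: {proc.stderr.strip()}")
            self._blast_db = workdir / self.name
        return self._blast_db


def build_repository(fasta, name: str,
                     procurement_cost: Optional[Decimal] = None) -> Repository:
    """Read a multi-FASTA into a repository; ids must be unique, sequences
    are upper-cased and non-ACGT codes are tolerated but logged."""
    path = Path(fasta)
    records: dict[str, RepoRecord] = {}
    duplicates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"{path}: empty sequence for record {rec.id!r}")
        if rec.id in records:
            duplicates.append(rec.id)
            continue
        if set(seq) - set("ACGT"):
            if not set(seq) <= IUPAC_DNA:
                raise InputError(f"{path}: record {rec.id!r} has non-IUPAC characters")
            log.warning("record %s contains ambiguity codes", rec.id)
        circular = "circular" in rec.description.lower()
        records[rec.id] = RepoRecord(rec.id, seq, circular, rec.description)
    if duplicates:
        raise InputError(f"{path}: duplicate record ids: {sorted(set(duplicates))}")
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return Repository(name=name, records=records,
                      procurement_cost=procurement_cost, fasta_path=path)


def exclude(repo: Repository, tokens: Iterable[str]) -> Repository:
    """A view of ``repo`` hiding records whose header contains any token
    (whitespace-delimited match); the original repository is unchanged."""
    tokens = [t for t in tokens if t]
    hidden = {
        rec.id for rec in repo.records.values()
        if any(tok in rec.tokens for tok in tokens)
    }
    return Repository(
        name=repo.name, records=repo.records,
        procurement_cost=repo.procurement_cost, fasta_path=repo.fasta_path,
        _excluded=repo._excluded | frozenset(hidden), _blast_db=repo._blast_db)


# --------------------------------------------------------------------------
# Feature database


@dataclass
class FeatureLookup:
    """Result of a feature-name lookup; a miss carries suggestions."""

    name: str
    sequence: Optional[str]
    suggestions: list[str] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.sequence is not None


class FeatureDB:
    """Case-insensitive name → sequence map loaded from 2-column TSV."""

    def __init__(self, entries: dict[str, str]):
        self._entries: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for name, seq in entries.items():
            key = name.casefold()
            if key in self._entries:
                raise InputError(f"duplicate feature name (case-folded): {name!r}")
            if not seq:
                raise InputError(f"empty sequence for feature {name!r}")
            self._entries[key] = seq.upper()
            self._display[key] = name

    def __len__(self) -> int:
        return len(self._entries)

    def names(self) -> list[str]:
        return sorted(self._display.values())

    @classmethod
    def from_tsv(cls, path) -> "FeatureDB":
        return cls(_read_tsv(path, "feature"))

    def to_tsv(self, path) -> None:
        with Path(path).open("w") as fh:
            for key in sorted(self._entries):
                fh.write(f"{self._display[key]}\t{self._entries[key]}\n")

    def add(self, name: str, sequence: str) -> None:
        key = name.casefold()
        self._entries[key] = sequence.upper()
        self._display[key] = name

    def delete(self, name: str) -> bool:
        key = name.casefold()
        existed = key in self._entries
        self._entries.pop(key, None)
        self._display.pop(key, None)
        return existed


def lookup_feature(name: str, db: FeatureDB) -> FeatureLookup:
    """Exact case-insensitive lookup; a miss returns nearest-name
    suggestions instead of raising."""
    key = name.casefold()
    seq = db._entries.get(key)
    if seq is not None:
        return FeatureLookup(name, seq)
    suggestions = difflib.get_close_matches(key, list(db._entries), n=3, cutoff=0.5)
    return FeatureLookup(name, None, [db._display[s] for s in suggestions])


# --------------------------------------------------------------------------
# Enzyme database and digestion


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str          # IUPAC site without the caret
    cut_offset: int           # top-strand cut position within the site

    @classmethod
    def from_notation(cls, name: str, notation: str) -> "Enzyme":
        if notation.count("^") != 1:
            raise InputError(
                f"enzyme {name!r}: recognition {notation!r} needs exactly one '^'")
        offset = notation.index("^")
        site = notation.replace("^", "").upper()
        if not site or not set(site) <= IUPAC_DNA:
            raise InputError(f"enzyme {name!r}: invalid IUPAC site {notation!r}")
        return cls(name, site, offset)

    @property
    def notation(self) -> str:
        return self.recognition[:self.cut_offset] + "^" + self.recognition[self.cut_offset:]


class EnzymeDB:
    def __init__(self, enzymes: dict[str, Enzyme]):
        self._enzymes = {name.casefold(): enz for name, enz in enzymes.items()}

    def __len__(self) -> int:
        return len(self._enzymes)

    def get(self, name: str) -> Optional[Enzyme]:
        return self._enzymes.get(name.casefold())

    def names(self) -> list[str]:
        return sorted(e.name for e in self._enzymes.values())

    @classmethod
    def from_tsv(cls, path) -> "EnzymeDB":
        raw = _read_tsv(path, "enzyme")
        return cls({n: Enzyme.from_notation(n, v) for n, v in raw.items()})

    def to_tsv(self, path) -> None:
        with Path(path).open("w") as fh:
            for key in sorted(self._enzymes):
                enz = self._enzymes[key]
                fh.write(f"{enz.name}\t{enz.notation}\n")

    def add(self, name: str, notation: str) -> None:
        self._enzymes[name.casefold()] = Enzyme.from_notation(name, notation)

    def delete(self, name: str) -> bool:
        return self._enzymes.pop(name.casefold(), None) is not None


class NoCutError(PlasmidPlanError):
    pass


@dataclass
class LinearFragment:
    """A digest product; ``left_end``/``right_end`` record the terminal
    sequence context for downstream junction design."""

    sequence: str
    left_end: str
    right_end: str


def _cut_positions(seq: str, enzyme: Enzyme, circular: bool) -> list[int]:
    """Top-strand cut coordinates for sites on both strands; reverse-strand
    sites cut at the mirrored offset."""
    n = len(seq)
    search = seq + seq[:len(enzyme.recognition) - 1] if circular else seq
    fwd = re.compile(iupac_pattern(enzyme.recognition))
    rev_site = revcomp(enzyme.recognition)
    rev = re.compile(iupac_pattern(rev_site))
    site_len = len(enzyme.recognition)
    cuts = set()
    for m in fwd.finditer(search):
        cuts.add((m.start() + enzyme.cut_offset) % n if circular
                 else m.start() + enzyme.cut_offset)
    palindromic = rev_site == enzyme.recognition
    if not palindromic:
        mirrored = site_len - enzyme.cut_offset
        for m in rev.finditer(search):
            cuts.add((m.start() + mirrored) % n if circular
                     else m.start() + mirrored)
    return sorted(c for c in cuts if 0 <= c <= (n if not circular else n - 1))


def digest_backbone(sequence: str, enzyme: Enzyme,
                    circular: bool = True) -> LinearFragment:
    """Digest a backbone and return the largest fragment.

    A circular backbone with k sites yields k fragments (their lengths sum
    to the backbone length); zero sites raise :class:`NoCutError`.
    """
    seq = sequence.upper()
    cuts = _cut_positions(seq, enzyme, circular)
    if not cuts:
        raise NoCutError(f"{enzyme.name} does not cut the backbone")
    fragments = digest_fragments(seq, cuts, circular)
    best = max(fragments, key=len)
    return LinearFragment(best, left_end=best[:20], right_end=best[-20:])


def digest_fragments(seq: str, cuts: list[int], circular: bool) -> list[str]:
    n = len(seq)
    if circular:
        frags = []
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            length = (nxt - c) % n or n
            frags.append((seq + seq)[c:c + length])
        return frags
    bounds = [0] + cuts + [n]
    return [seq[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]


def anneal_to_backbone(insert: str, backbone: LinearFragment) -> str:
    """Circular target = insert followed by the linearized backbone."""
    if not insert:
        raise InputError("empty insert")
    if not backbone.sequence:
        raise InputError("empty backbone fragment")
    return insert.upper() + backbone.sequence


def _read_tsv(path, kind: str) -> dict[str, str]:
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
        name, value = parts[0].strip(), parts[1].strip()
        if not name or not value:
            raise InputError(f"{path}:{lineno}: empty {kind} name or value")
        entries[name] = value
    return entries


_DATA_DIR = Path(__file__).parent / "data"


def default_feature_db() -> FeatureDB:
    return FeatureDB.from_tsv(_DATA_DIR / "features.tsv")


def default_enzyme_db() -> EnzymeDB:
    return EnzymeDB.from_tsv(_DATA_DIR / "enzymes.tsv")
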