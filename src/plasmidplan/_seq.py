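"""Low-level sequence helpers shared across the package.

Circular coordinates are handled by slicing on the doubled (or tripled)
sequence; all spans are 0-based half-open.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)

IUPAC_DNA = set("ACGTMRWSYKVHDBN")

_IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def is_iupac_dna(seq: str) -> bool:
    return bool(seq) and set(seq.upper()) <= IUPAC_DNA


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice a circular sequence; ``start``/``end`` may exceed ``len(seq)``
    or be negative, and the span may wrap the origin (requires
    ``end - start <= len(seq)`` is *not* enforced: spans longer than one
    lap repeat the sequence)."""
    n = len(seq)
    if n == 0:
        return ""
    if end < start:
        raise ValueError(f"inverted span [{start}, {end})")
    length = end - start
    pos = start % n
    doubled = seq + seq
    out = []
    remaining = length
    while remaining > 0:
        take = min(remaining, 2 * n - pos)
        out.append(doubled[pos:pos + take])
        remaining -= take
        pos = (pos + take) % n
    return "".join(out)


def min_rotation(seq: str) -> int:
    """Index of the lexicographically smallest rotation (two-pointer
    comparison on the doubled string, O(n))."""
    s = seq + seq
    n = len(seq)
    i, j, k = 0, 1, 0
    while i < n and j < n and k < n:
        a, b = s[i + k], s[j + k]
        if a == b:
            k += 1
            continue
        if a > b:
            i = i + k + 1
        else:
            j = j + k + 1
        if i == j:
            j += 1
        k = 0
    return min(i, j)


def canonical_rotation(seq: str) -> str:
    """Rotate a circular sequence so its lexicographically smallest rotation
    starts at index 0; makes equivalent circular inputs comparable."""
    if not seq:
        return seq
    k = min_rotation(seq)
    return seq[k:] + seq[:k]


def rotations_equal(a: str, b: str) -> bool:
    """True if two circular sequences are identical up to rotation."""
    return len(a) == len(b) and (not a or a in b + b)


def iupac_pattern(site: str) -> str:
    """Regex character-class pattern for an IUPAC recognition site."""
    parts = []
    for ch in site.upper():
        exp = _IUPAC_EXPAND.get(ch)
        if exp is None:
            raise ValueError(f"invalid IUPAC base {ch!r} in {site!r}")
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best
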