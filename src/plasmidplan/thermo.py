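"""Nearest-neighbor DNA thermodynamics for primer and fragment screening.

Three predictions back the design rules:

* ``binding_tm`` — melting temperature of a primer's template-binding
  region, SantaLucia (2004) unified NN parameters under PCR-like salt
  (50 mM monovalent, 1.5 mM Mg2+, 0.6 mM dNTPs, 50 nM oligo).
* ``ectopic_duplex_tm`` — end-anchored duplex Tm between a primer and a
  candidate off-target site. Polymerase extension requires a paired 3'
  terminus, so the prediction scores the longest contiguous perfectly
  paired block anchored at the primer's 3' end; a mismatched 3' terminus
  or a block shorter than 8 bp yields 0 °C.
* ``hairpin_tm`` — unimolecular hairpin melting temperature at a fragment
  end: the strongest self-complementary stem (≥4 bp, loop ≥3 nt) within
  the terminal window, Tm = ΔH/(ΔS + ΔS_loop) with a hairpin-loop
  entropy penalty.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.SeqUtils import MeltingTemp as mt

from ._seq import complement, revcomp

# PCR-like conditions used for every bimolecular Tm.
_SALT = dict(Na=50, K=0, Tris=0, Mg=1.5, dNTPs=0.6, dnac1=50, dnac2=0, saltcorr=7)

# Hairpin-loop free-energy penalties ΔG37 (kcal/mol) by loop size
# (SantaLucia & Hicks 2004); intermediate sizes interpolate, larger
# sizes extrapolate logarithmically via the last entry.
_LOOP_DG37 = {3: 3.5, 4: 3.5, 5: 3.3, 6: 4.0, 7: 4.2, 8: 4.3, 9: 4.5,
              10: 4.6, 12: 5.0, 14: 5.1, 16: 5.3, 18: 5.5, 20: 5.7,
              25: 6.1, 30: 6.3}

_T37 = 310.15


@lru_cache(maxsize=100_000)
def binding_tm(seq: str) -> float:
    """Tm (°C) of a perfectly matched primer-template duplex."""
    if len(seq) < 2:
        return -273.15
    return float(mt.Tm_NN(seq, **_SALT))


def ectopic_duplex_tm(primer: str, site: str) -> float:
    """End-anchored Tm (°C) of a primer annealed to a putative site.

    ``site`` is the target-strand sequence the primer would occupy (equal
    length, aligned so its last base sits under the primer's 3' end).
    """
    n = min(len(primer), len(site))
    if n == 0:
        return 0.0
    p = primer[-n:].upper()
    s = site[-n:].upper()
    run = 0
    for a, b in zip(reversed(p), reversed(s)):
        if a == b and a in "ACGT":
            run += 1
        else:
            break
    if run < 8:
        return 0.0
    return binding_tm(p[-run:])


def _nn_step(x: str, y: str) -> tuple[float, float]:
    """(ΔH kcal/mol, ΔS cal/mol/K) for the perfect-match NN step 5'-xy-3'."""
    table = mt.DNA_NN3
    key = f"{x}{y}/{complement(x)}{complement(y)}"
    if key in table:
        return table[key]
    alt = f"{complement(y)}{complement(x)}/{y}{x}"
    return table[alt]


def _loop_ds(size: int) -> float:
    """Loop entropy penalty (cal/mol/K, negative) for a hairpin loop."""
    sizes = sorted(_LOOP_DG37)
    if size <= sizes[0]:
        dg = _LOOP_DG37[sizes[0]]
    elif size >= sizes[-1]:
        dg = _LOOP_DG37[sizes[-1]]
    else:
        lo = max(s for s in sizes if s <= size)
        hi = min(s for s in sizes if s >= size)
        if lo == hi:
            dg = _LOOP_DG37[lo]
        else:
            frac = (size - lo) / (hi - lo)
            dg = _LOOP_DG37[lo] + frac * (_LOOP_DG37[hi] - _LOOP_DG37[lo])
    return -dg * 1000.0 / _T37


def _stem_tm(stem: str, loop: int) -> float:
    """Unimolecular Tm (°C) of a perfect hairpin stem with a given loop."""
    dh = 0.2    # duplex initiation
    ds = -5.7
    stem = stem.upper()
    if any(c not in "ACGT" for c in stem):
        return -273.15
    for i in range(len(stem) - 1):
        h, s = _nn_step(stem[i], stem[i + 1])
        dh += h
        ds += s
    ds += _loop_ds(loop)
    if ds >= 0:
        return -273.15
    return dh * 1000.0 / ds - 273.15


def hairpin_tm(seq: str, window: int = 50, min_stem: int = 5,
               min_loop: int = 3, end_zone: int = 15) -> float:
    """Predicted Tm (°C) of the strongest hairpin that sequesters the 3'
    terminus of ``seq``; 0 °C when none forms.

    Only stems whose 3' arm reaches into the terminal ``end_zone`` bp
    matter: a folded-back terminus blocks the exonuclease chew-back and
    annealing of the junction homology, whereas structure deeper inside
    the fragment does not. Stems are searched within the last ``window``
    bp.
    """
    s = seq[-window:].upper() if len(seq) > window else seq.upper()
    n = len(s)
    best = 0.0
    # stems: arm1 = s[i:i+k] pairs arm2 = s[j:j+k] (arm1 == revcomp(arm2))
    # with loop j - (i + k) >= min_loop and arm2 ending in the 3' zone
    for k in range(min_stem, n // 2 + 1):
        found = False
        for j in range(max(0, n - end_zone - k + 1), n - k + 1):
            arm2_rc = revcomp(s[j:j + k])
            start = 0
            while True:
                i = s.find(arm2_rc, start, j)
                if i == -1:
                    break
                loop = j - (i + k)
                if loop >= min_loop:
                    found = True
                    tm = _stem_tm(s[i:i + k], loop)
                    best = max(best, tm)
                start = i + 1
        if not found:
            break
    return best
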