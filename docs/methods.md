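# Methods

This note documents the model behind `plasmidplan`, the defaults it
ships with, the numerical choices buried in the implementation, and
what the synthetic test fixtures do and do not demonstrate.

## Design model

A design instance is a circular target sequence of length *L* plus a
set of fragment repositories. The designer's objective is the Pareto
front over two conflicting goals: total monetary cost and number of
build fragments. A solution is an ordered set of fragments — PCR
amplicons from repository plasmids, synthetic spans, or a single
existing plasmid — whose adjacent ends (cyclically) share an exact
homology overlap suitable for Gibson assembly.

Inputs are canonicalized by rotating the circle so its
lexicographically smallest rotation starts at index 0; equivalent
circular inputs therefore produce byte-identical output. All
coordinates are 0-based half-open spans on the doubled sequence axis
`[0, 2L)`, which turns origin-spanning fragments into ordinary
intervals.

### Search

The doubled target is queried against each repository. Two backends
share one result model:

* `blast` — shells out to `makeblastdb`/`blastn` (task `blastn`,
  tabular output, one thread for determinism). Reward/penalty/gap-open/
  gap-extend follow the requested percent identity through a small
  table (nearest row at or below the request): 50% → (1, −1, 2, 1),
  90% → (1, −2, 1, 2), 95% → (2, −3, 4, 2). Requests above 99% switch
  to (1, −6, 6, 6): the harsh penalties suppress frayed, imperfect hit
  ends that otherwise survive at default scoring.
* `kmer` — an in-process seed-and-extend matcher (12-mer seeds, maximal
  exact extension, both strands) that reports exact matches at 100%
  identity. It exists so designs, tests, and batch sweeps run without
  spawning external processes; it is the default in the test suite and
  the acceptance script, where fixtures plant exact-match fragments.
  The BLAST backend remains the production path for real repositories,
  where matches below 100% identity matter.

Matches whose query span is properly contained in another's are culled;
equal spans keep the lexicographically first (repository, entry) for
determinism. Hits longer than *L* are truncated to *L*.

### Traversal

Matches starting in `[0, L)` seed chains. A chain grows by annealing
any match with a strictly larger start, closes once it spans ≥ *L* from
its seed, and is kept if its fragment count (matches + estimated
synthetic fragments) stays within `max-fragment-count` (default 6).
Coverage gaps contribute `ceil(gap / max-synthetic-length)` estimated
synthetic fragments; gaps ≤ 20 bp contribute none, since they are later
embedded in primer tails. Rotation-equivalent chains (the same
fragments discovered from different seeds) are emitted once. Each
candidate carries a pre-fill cost estimate — synthesis for its gaps,
procurement for its distinct sources, a nominal 2 × 25 bp primer pair
per PCR fragment, PCR buffer, and one Gibson charge. A second, strictly
lower-bound variant of the estimate (primer floor 2 × 18 bp, the
minimum binding length) drives the fill loop's early-exit test, so the
skip rule can never discard a candidate that might still enter the
Pareto front.

### Filling

Junction resolution works on target coordinates. With native overlap
`o = left.end − right.start`:

* `o > 150` — the later (3′) fragment's start is trimmed first (keeps
  seed coordinates stable); the earlier fragment absorbs any remainder.
* `o < 15` — the deficit (including a gap of up to 20 bp, whose
  sequence is thereby embedded in the primers) is added as 5′ primer
  tails, split ceil-left/floor-right between two PCR fragments, or
  placed entirely in the synthetic side when one side is synthetic.
* surplus homology (`15 < o ≤ 150`) becomes primer flexibility: the
  slack is split between the two sides (all of it to the PCR side at a
  PCR–synthetic junction) and each primer may slide its binding site
  into the surplus, choosing the shortest viable binding region. This
  both cuts primer cost and rescues ends whose immediate boundary is
  AT-rich or repetitive.

Primer binding regions grow from 18 bp until the SantaLucia
nearest-neighbor melting temperature (50 mM Na⁺, 1.5 mM Mg²⁺, 0.6 mM
dNTPs, 50 nM oligo) reaches 57 °C, capped at 30 bp and 72 °C; regions
containing a homopolymer run longer than 8 bp are rejected. Reported
primer Tm covers the binding region only, never the tail. A fragment
end with no viable binding region fails the candidate (a typed failure
value, not an exception — the driver moves on).

Every primer is screened for ectopic sites by scanning both strands of
the build's source plasmids for windows ≥ 65% identical to the primer.
Hits inside any build fragment's amplified span are intended material —
binding sites and shared junction homology (neighboring fragments
legitimately carry the same junction sequence) — and are not ectopic;
any other hit is scored by end-anchored duplex Tm, and a site above
`pcr-primer-max-ectopic-tm` (default 45 °C) rejects the candidate. The
end-anchored duplex Tm is computed as the nearest-neighbor Tm of the
longest contiguous perfectly paired block anchored at the primer's 3′
end (0 °C below 8 bp): a mispriming event requires an extensible 3′
terminus, so 3′-mismatched look-alikes score as harmless.

Synthetic spans include their junction homology, are grown
symmetrically into neighboring homology when shorter than
`min-synthetic-length` (default 125 bp), and are split into near-equal
sub-fragments sharing `min-homology` overlaps when longer than
`max-synthetic-length` (default: the largest cost-curve threshold).
Every synthetic 3′ end is folded with a unimolecular hairpin model: the
strongest stem (≥ 5 bp, loop ≥ 3 nt) whose 3′ arm reaches into the
terminal 15 bp, with Tm = ΔH/(ΔS + ΔS_loop) from the unified
nearest-neighbor parameters plus a hairpin-loop entropy penalty. Only
terminus-sequestering stems are screened because a fold deeper inside
the fragment does not block chew-back and annealing of the junction
homology. While the predicted Tm exceeds `fragments-max-hairpin-tm`
(default 47 °C) the 3′ end is extended in 5 bp strides (at most 10,
never past the homology cap or the synthesis cap), re-folding after
each stride; persistent hairpins fail the candidate with a typed
reason. On random sequence this screen triggers for roughly 5% of
fragment ends and almost always clears within one or two strides.

A single match covering ≥ 99.9% of both the target and its source
record short-circuits to an "existing plasmid" solution: procurement
cost only, no PCR, no Gibson. A full-length match inside a longer
record is instead amplified with self-circularization homology in its
primers.

### Pareto selection

Filled solutions are reduced to the antichain under (cost, fragment
count) dominance, processed in ascending (estimated cost, count) order.
A candidate is skipped outright when an already-kept solution has both
cost ≤ its lower-bound estimate and count ≤ its fragment count — the
filled result could then never be non-dominated. The all-synthetic
design is always a candidate, so repository re-use must beat synthesis
to be reported, and the cheapest returned solution can never exceed the
all-synthetic price.

## Costs

Money is exact decimal, quantized to cents. Synthesis price curves are
tiered maps from an integer length threshold to a fixed price or a
per-bp rate; the first threshold at or above the span length applies
(a 500 bp span is priced by the 500 bp tier — the threshold is read as
the largest length the tier covers), and spans beyond the last
threshold must be split before pricing. The shipped defaults are
placeholder provider prices and should be replaced with current quotes:

* fragments: 250/500 bp → $89 fixed, 750 → $149, 1000 → $179,
  1500 → $269, 2000 → $349, 3000 → $0.20/bp;
* genes (pre-cloned): $0.89/bp up to 3000 bp.

Primers cost $0.60/bp over their full length (tails included), PCR
buffer $0.27 per PCR fragment, Gibson master mix $12.98 per assembly.
Procurement is one flat charge per distinct source plasmid per design
($0 iGEM and user databases, $65 Addgene, $55 DNASU); two fragments
amplified from the same plasmid incur it once. Two human-labor knobs
(per batched PCR, per Gibson) default to $0. An existing-plasmid
solution pays procurement only.

## Synthetic fixtures and what they show

The fixture generator plants repository fragments as verbatim spans of
a seeded random circle (1.2–2.6 kb, 2–4 fragments, designed 18–60 bp
junction overlaps, optionally one 30–300 bp synthesis gap), plus decoy
records drawn from an independent stream and rejected until they share
no 15-mer with the target on either strand. Hazard variants replicate a
fragment's 5′ primer site elsewhere in its record, plant a perfect 20
bp palindrome at a junction, or place the only covering fragment across
the circular origin.

Passing the suite on these fixtures demonstrates the combinatorial and
bookkeeping machinery: exact junction homology, reconstruction of the
target by simulated assembly, true cost minimality against exhaustive
enumeration (≤ 12 matches), hazard avoidance, and determinism. It does
not demonstrate behavior on real repository data, where matches are
imperfect (the amplicon then differs from the target at mismatched
positions — the design assumes repository identity is acceptable at the
user's chosen threshold), where repetitive sequence inflates the match
set, and where synthesis-complexity constraints (which this tool does
not model) limit orderable fragments.

The brute-force oracle shares the fill routine with the pipeline by
design — it independently re-enumerates *chains*, so it checks the
traversal and Pareto machinery, not the fill arithmetic; fill
correctness is covered separately by the junction/reconstruction
oracles, which depend on nothing but string equality.

## Known limitations and deliberate choices

* Melting temperatures come from the package's own nearest-neighbor
  implementation (Biopython parameter tables); absolute values can
  differ by a few degrees from other thermodynamic engines, so the
  ectopic/hairpin thresholds should be read as calibrated to this
  model rather than as portable physical constants.
* The ectopic screen treats every build source as if co-present in one
  reaction (conservative for batched PCR) but exempts amplified spans;
  a repeat *inside* one amplicon is not separately flagged.
* Per-fragment fill results are recomputed per candidate rather than
  cached across candidates; at the problem sizes the tool targets
  (≤ 6 fragments, repositories of 10²–10⁵ records) filling is
  dominated by the search step, so the cache was not worth its
  invalidation complexity.
* Adding repository material can, in one corner case, reshuffle which
  match survives engulfment culling and shift primer binding sites by
  a few bases, changing the cheapest price by a few dollars in either
  direction; adding a fragment that does not fully engulf an existing
  match strictly enlarges the candidate pool and can only lower the
  cheapest price.
* Bulk-order discounts, provider web-API pricing, Addgene's for-profit
  restrictions, Golden Gate assembly, and synthesis-complexity
  screening are out of scope.
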