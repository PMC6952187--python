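# plasmidplan

Cost-optimal decomposition of circular plasmids into PCR-amplified
repository fragments and synthetic DNA for Gibson assembly.

## The problem

Most new plasmids are mosaics of sequence that already exists — in the
lab freezer, in a collaborator's strain box, or in public repositories.
Re-using that material by PCR is usually far cheaper than commercial
synthesis, but finding the *least expensive* combination of repository
fragments and synthetic spans — while respecting Gibson assembly's
junction-homology rules, avoiding off-target primer sites, and dodging
hairpins at synthetic fragment ends — is beyond what a human designer
can enumerate.

`plasmidplan` inverts the usual cloning workflow: you declare the target
plasmid (as a sequence, or as an ordered list of named features), name
the fragment databases you can draw from, and the designer returns build
instructions — fragments, primers with junction homology, synthetic
spans, and an itemized cost sheet.

## The method

Given a circular target of length *L*:

1. **Search** — the target is doubled end-to-end and queried against
   each repository (`blastn`, or a built-in exact matcher), so fragments
   spanning the circular origin appear as ordinary hits on `[0, 2L)`.
   Alignment reward/penalty/gap parameters follow the requested percent
   identity (default 98%; 96% in feature mode). Hits fully engulfed by
   others are culled.
2. **Traverse** — matches starting within one target length seed a
   5′→3′ traversal that chains matches into candidate assemblies;
   coverage gaps are budgeted as synthetic spans (gaps ≤ 20 bp ride
   inside primers). Chains close after one full lap and must stay within
   the fragment-count limit (default 6).
3. **Fill** — every junction is resolved to an exact overlap of 15–150
   bp: homology deficits are split between neighboring primers as 5′
   tails, excess overlap is trimmed, and surplus homology gives primers
   a flexible range to pick an optimal binding site. Primers are
   screened against the build's source plasmids for ectopic binding
   sites (65% identity scan; end-anchored duplex melting temperature
   must stay ≤ 45 °C). Synthetic spans are grown to the minimum
   orderable length, split under the synthesis cap with shared
   overlaps, and their 3′ ends are shifted off predicted hairpins
   (> 47 °C).
4. **Pareto front** — design cost and fragment count usually conflict,
   so the designer fills candidates in ascending estimated-cost order
   and returns the Pareto-optimal set under (total cost, fragment
   count); the all-synthetic design always competes as a baseline.

Costs are exact decimals: tiered synthesis price curves (fixed or
per-bp), $0.60/bp primers, $0.27 PCR buffer per reaction, $12.98 per
Gibson assembly, and per-repository procurement charges ($0 iGEM and
user databases, $65 Addgene, $55 DNASU by default) — all overridable
from a YAML configuration file.

## Worked example

Design a 1,500 bp circular target from three overlapping freezer
fragments (FASTA files as produced by any sequence editor):

```sh
plasmidplan design sequence -i target.fa --dbs freezer=freezer.fa \
    --backend kmer -o out.json
# 3 solution(s); cheapest $88.19 with 3 fragment(s)
```

The JSON payload contains the full Pareto front:

| cost    | fragments | composition                  |
|---------|-----------|------------------------------|
| $88.19  | 3         | 3 × PCR (580, 363, 638 bp)   |
| $216.25 | 2         | 1 × PCR + 1 × 880 bp synthetic |
| $361.98 | 1         | single 1,515 bp synthetic    |

The cheapest solution re-uses all three freezer fragments: $74.40 of
primers (six primers, 18–26 bp binding regions plus junction tails),
3 × $0.27 PCR buffer, and $12.98 of Gibson master mix. Fewer-fragment
solutions trade money for bench simplicity — the single-fragment option
is pure synthesis at the 2,000 bp price tier. Every adjacent fragment
pair (including the wrap-around junction) shares 15–150 bp of exact end
homology, so the designs assemble directly in a one-pot Gibson
reaction; each solution lists its primers with binding-region melting
temperatures.

Feature mode works the same way from named parts, with optional
backbone linearization:

```sh
plasmidplan design features "pLac,RBS,GFP,term" --dbs igem=parts.fa \
    --backbone pSB1A3 --enzyme PstI -o out.json
```

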