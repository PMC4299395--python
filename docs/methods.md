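# Methods

## The identifier grammar

A locus identifier concatenates six elements:

| element | form | notes |
|---|---|---|
| taxon code | 5–6 letters | `VITVI` for *V. vinifera*; `VIT`+catalogue code (e.g. `VITVBR`) for other *Vitis* species |
| chromosome | 2 digits, 00–19 | `00` = unanchored scaffold bin |
| object type | 1–2 lowercase letters | `g t p nc tr te rr mi ps si sn` |
| numeric code | 5 digits, 00001–99999 | sequential per chromosome, `+1`, no gaps |
| variant | `-` + lowercase letters + optional digit run | splice digits only on `t`/`p` objects |
| version | `.` + integer ≥ 1 | absent = most recent |

Parsing is case-insensitive on the taxon code; canonical output renders it
title-case (`Vitvi18g12230`). An absent version is stored as *absent*, not
defaulted to 1, so `parse ∘ format` is the identity on every valid
identifier (property-tested on seeded random identifiers, and fuzzed with
single-character mutations of a canonical string, each of which either
parses or raises one specific named error). Allele-letter variants without
a splice digit are admitted on any object type: the grammar restricts only
the splice digits to transcripts and proteins, and an allele can exist at
a locus regardless of the object recorded. The legacy 12X-v1 shape
(`VIT06s0009g01380`) is parsed only so historical identifiers can be
stored as synonyms — mapping legacy to current identifiers is data, not
grammar, and is out of scope.

## The registry

The registry is event-sourced: every mutation first constructs an
`AnnotationEvent` and then applies it through the same pure state
transition used by `Registry.replay`, so replaying the log from an empty
registry reproduces the live state exactly (asserted bit-for-bit on a
canonical state snapshot after randomized operation sequences). Events are
append-only and never modified.

Decisions taken where the rules leave room:

- **One counter per chromosome, shared across object types.** The 5-digit
  space is "per chromosome for all objects"; a shared counter keeps the
  no-reuse guarantee trivially true across types.
- **Merge survivor is caller-chosen**; the CLI defaults to the lower
  numeric code. Cross-chromosome merges are rejected — relocate first, so
  each event has single-purpose semantics.
- **Split keeps the original identifier** (version-bumped, since its
  structure changed); only the additional models receive fresh
  identifiers.
- **Relocation starts the new record at version 1** and carries names and
  synonyms over; the full history stays attached to the retired
  identifier and remains retrievable. The synonym stores the bare old
  locus identifier, without a version suffix.
- Synonym `(name, kind)` pairs are unique per gene, case-insensitively on
  the name; notes use the controlled vocabulary
  `obsolete | incorrect | ambiguous` plus free text, with an optional
  bibliographic token.
- GO evidence handling is limited to recording a free-text evidence-code
  string when at least some experimental functional evidence exists; no
  ontology validation is attempted.

Persistence is three plain-text files (`registry.tsv`, `synonyms.tsv`,
`events.jsonl`); loading replays the event log, which is the source of
truth.

## The confidence classifier

The classifier is a fixed-precedence decision ladder over an evidence
bundle:

```
uncertain (pseudogene) ≻ named ≻ probable ≻ putative
        ≻ similar to ≻ domain containing ≻ expressed ≻ hypothetical
```

with `translated` stacked as an orthogonal qualifier whenever
protein-level evidence exists (it proves existence, not function). The
ladder is this package's own reconstruction from the definitions of the
levels, and is stated as such.
Similarity-based levels (`similar to`, `domain containing`) require
transcript evidence first: a locus leaves `hypothetical` only once an RNA
is proven. `putative` strictly requires in-silico functional evidence and
`probable` at least some experimental evidence; neither is inferred from
homology alone.

Tie conventions follow the stated wording literally: e-value cutoff
inclusive (≤ 1e-20), identity and length inclusive (≥ 30 %, ≥ 80 aa),
name transfer strictly exclusive (> 95 %). Among multiple hits the single
best decides: smallest e-value, ties broken by higher identity, longer
alignment, then lexical subject name. `scan_threshold_boundary` recovers
these boundaries behaviourally (largest passing e-value, smallest passing
identity, largest refused transfer identity) and round-trips any
configured `ConfidenceThresholds`; classification is total, deterministic,
and monotone under single-axis evidence improvement (property-tested).

## Tree preprocessing and orthology

`collapse_weak_branches` contracts every internal edge with support
strictly below the threshold (default 70 %; support exactly 70 is
retained), forming polytomies. Leaves and their annotations are
invariant; the operation is idempotent. Unlabelled internal edges are
retained, on the view that absent support is not evidence of weakness.

Ortholog relations use the **species-overlap** rule on the collapsed
input tree: an internal node is a duplication iff at least two of its
child subtrees share a species; a grapevine and an *Arabidopsis* leaf are
orthologs iff their last common ancestor is a speciation node. Relation
classes count both sides of the bipartite ortholog graph, so a grapevine
gene whose single ortholog is shared with another grapevine gene is
one2many, not one2one. This is a deliberate lightweight approximation of
a full gene-tree/species-tree reconciliation pipeline; on curated,
collapsed family trees with one focal and one reference species the two
agree, and the implementation is checked against an independent
brute-force pairwise oracle — exhaustively on every rooted binary
two-species topology and species assignment up to 5 leaves, and on a
seeded random sample of 6- and 7-leaf trees (the exhaustive 6–7-leaf
space, over a million trees, adds no structural cases beyond what the
sample covers; the sizes here are the package's chosen test scale).

## The symbol-proposal engine

Proposals are produced per family run, processing grapevine leaves in the
tree's written (drawn) left-to-right order. Since there is explicitly no
inherent order in which tied genes must be named, the input order — the
order a curator sees in the drawn tree — is used as the
deterministic tiebreak; identical inputs always give identical output.

Rule order, first match wins (the fired rules are recorded per proposal
as its rationale trail):

1. **phenotype-name** — a grapevine mutant-phenotype name supplied for the
   gene wins outright (even if it violates symbol-length conventions; the
   violation is attached to the proposal rather than blocking it).
2. **equal-distance-letters** — ≥ 2 grapevine genes unresolved against a
   single numbered reference gene share its designator with letter
   suffixes `a, b, …` in traversal order. "Equally distant" is
   operationalized structurally: the members share a parent node and
   their unique topologically nearest reference leaf is the same gene at
   most three edges away (same polytomy, or attached just outside the
   cherry). Letters run per reference gene across all such sibling
   groups, so designators stay unique even when several polytomies
   surround one reference gene. A member whose historical symbol fits the
   family format under a *different* designator is excluded (its history
   shows it is not part of that subgroup).
3. **keep-historical** — an existing symbol that already fits the family
   format and is free is kept (`SUC11`, `CCD8b`). If two genes claim the
   same historical symbol, the first in traversal order keeps it and the
   second falls through to a fresh number with the ambiguous name as a
   synonym.
4. **adopt-ortholog-symbol** — a one2one ortholog of a reference gene
   whose symbol fits the family format adopts it (`STP1`).
5. **off-root-ortholog** — a one2one ortholog of a phenotype-named or
   otherwise off-root reference gene (`EIN3`, `SLIM1`) takes the next
   free number; the off-root name is registered as a synonym.
6. **next-number** — everything else (one2many, many2many, none) takes
   `max(designators used in either species) + 1`, capacity 999. With
   leaves processed in traversal order this automatically numbers a
   family absent from the reference species by the tree, never by
   chromosome position.

When the family root itself ends in a digit, an `L` (for "-like") is
inserted between root and designator (`ERD6` → `ERD6L1`); an explicit
override exists for families whose community chose otherwise. Every
displaced historical name becomes a synonym with an `obsolete` note;
symbol collisions within the focal species raise an error, while sharing
a symbol string with the reference species is exactly the intended
cross-species correspondence. The `Vvi` display prefix (chosen over the
`vv`/`Vv` prefixes, which collide with *Vibrio vulnificus* entries in
sequence databases) is applied only at rendering and never stored.

## The scenario fixtures

The worked scenarios (EIL, SUC, STP, ERD6-like, CCD, STS) are encoded
from the textual statements of the community nomenclature guidelines'
worked examples, not re-derived from sequences; each scenario tree
contains the minimal structure that carries the
stated relations (a one2one EIN3 ortholog, the EIL2-adjacent unresolved
pair, the orphan SUT2 gene, the duplicated CCD1 pair, the reference-free
STS family, a representative subset of the ERD6-like members). Gene
identifiers printed in the examples are used where given; the remaining
identifiers and supports are plausible placeholders. What passing the
scenario suite shows is that the rule engine reproduces the recommended
symbols on trees encoding those statements; it does not show
anything about trees inferred from real sequence data, where support
values, rogue taxa and deeper paralogy histories can move genes between
rules.

`random_family` builds two-species trees from speciation cherries plus
seeded duplications (supports uniform on [50, 100]) — by construction at
duplication rate 0 every relation is one2one or none, which anchors the
property tests. `random_registry` populates a registry exclusively
through `create_gene` in a seeded interleaved order, so all lifecycle
invariants hold by construction and the event log replays exactly. Both
generators are pure functions of their seed.

## Known limitations

- Orthology is species-overlap on the input tree; no species-tree
  reconciliation, no duplication-confidence scores, one reference species
  per run.
- The classifier consumes precomputed evidence; it runs no similarity
  searches or domain scans.
- The registry is single-writer; no locking or concurrent curation.
- Codon-level alignment guidance for building the input trees concerns an
  upstream step outside this package and is recorded here only for
  completeness.
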