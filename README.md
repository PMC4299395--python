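# vitinom

A toolkit for the standardized grapevine (*Vitis vinifera*) gene
nomenclature: stable locus identifiers with full lifecycle semantics, an
evidence-based confidence classifier for functional annotations, and a
phylogeny-driven gene-symbol proposal engine.

## Who this is for

Curators and bioinformaticians maintaining a community genome annotation
for grapevine (or a similarly structured crop genome) who need to

- issue and track **locus identifiers** of the form
  `Vitvi18g12230` — taxon code, chromosome (00–19, where 00 is the
  unanchored-scaffold bin), object type (`g`, `t`, `p`, `nc`, `tr`, `te`,
  `rr`, `mi`, `ps`, `si`, `sn`), a five-digit numeric code, an optional
  sequence variant (`-tpa2`) and an optional version (`.3`) — with the
  guarantee that identifiers are **never reused** across merges, splits and
  relocations, and that the registry's entire history replays from its
  append-only event log;
- classify the **confidence level** of a functional annotation
  (hypothetical → expressed → domain containing → similar to → putative →
  probable → named, with *uncertain* for pseudogenes and *translated* as an
  orthogonal existence qualifier) from homology, expression, protein and
  domain evidence;
- propose **gene symbols** (a 2–5 letter family root plus a 1–3 digit locus
  designator, e.g. `EIL3`, `SUC28`, `ERD6L2`) from a bootstrap-labelled
  gene tree shared with *Arabidopsis thaliana*, keeping every historical
  name as a tracked synonym.

## The rules at the core

**Identifiers.** Numbering per chromosome is strictly `+1` with no gaps
and capacity 99,999. A merge retires one identifier into the survivor's
synonym list; a split gives only the *new* models fresh identifiers; a
relocation (e.g. off chromosome 00 once a scaffold is placed) issues a new
identifier and retires the old one as a synonym. Any structural edit
increments the version by exactly 1; an identifier without a version
suffix means "most recent".

**Confidence.** The similarity criterion is the classical safe zone:
best-hit e-value ≤ 1e-20, or ≥ 30 % identity over ≥ 80 contiguous amino
acids. Direct transfer of a characterized grapevine protein's name
requires > 95 % whole-sequence identity.

**Symbols.** Branches with bootstrap support below 70 % are collapsed into
polytomies first. Ortholog relations are derived by the species-overlap
rule (an internal node is a duplication iff two of its child subtrees
share a species). Only a one2one ortholog may adopt its *Arabidopsis*
counterpart's symbol; everything else takes the next designator above the
highest number used in *either* species. Two or more grapevine genes
unresolved against a single numbered reference gene share its designator
with letter suffixes (`EIL2a`, `EIL2b`); a family root ending in a digit
gets an `L` inserted (`ERD6L1`); a family absent from *Arabidopsis* is
numbered by tree traversal, never by chromosome position. The `Vvi`
species prefix is display-only and never stored in the symbol.

## Worked example

```python
from vitinom import (GeneTree, FamilyRegistry, collapse_weak_branches,
                     infer_orthology, apply_family_naming)

newick = ("((Vitis_vinifera|VvGene1|,Arabidopsis_thaliana|AT3G20770|EIN3|P)95,"
          "(Vitis_vinifera|VvGene2|,Arabidopsis_thaliana|AT2G27050|EIL1)65);")
tree = collapse_weak_branches(GeneTree.from_newick(newick))  # 65 collapses
family = FamilyRegistry.from_symbols(
    "EIL", {"Vitis_vinifera": [],
            "Arabidopsis_thaliana": ["EIN3", "EIL1", "EIL2", "SLIM1"]})
relations = infer_orthology(tree, "Vitis_vinifera", "Arabidopsis_thaliana")
for p in apply_family_naming(family, tree, relations,
                             "Vitis_vinifera", "Arabidopsis_thaliana"):
    print(p.gene_id, p.symbol, [s.name for s in p.synonyms_to_register],
          p.rationale)
```

prints

```
VvGene1 EIL3 ['EIN3'] ['off-root-ortholog', 'next-number']
VvGene2 EIL4 [] ['next-number']
```

`VvGene1` is a one2one ortholog of *EIN3*, but *EIN3* is a phenotype name
off the family root, so the gene takes the next free designator (3, since
*EIL1* and *EIL2* are taken) and `EIN3` is registered as a synonym.
`VvGene2` lost its resolved placement when the 65 %-support branch was
collapsed, so it takes the next number after that, 4.

The same operations are available from a shell:

```
vitinom parse Vitvi18g12230
vitinom create --registry ./reg --chromosome 18
vitinom collapse --tree family.nwk --threshold 70
vitinom propose --tree family.nwk --family family.tsv --root EIL --prefix Vvi
vitinom fixtures --out scenarios/
```

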