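"""Worked naming scenarios and randomized instances.

Each scenario encodes, from the textual statements of the community
nomenclature guidelines' worked examples, a small family tree, the family's symbol registry, the historical
names involved, and the symbols the naming rules should produce:

- **EIL**: a grapevine one2one ortholog of the phenotype-named *EIN3*
  becomes ``EIL3`` (with ``EIN3`` as synonym); an unresolved pair adjacent
  to *EIL2* becomes ``EIL2a``/``EIL2b``; a gene equidistant from several
  unresolved family members takes the next free number, ``EIL4``.
- **SUC** (sucrose transporters): historical ``SUC11/12/27`` are kept
  (``SUT1`` folded in as a synonym of ``SUC11``); the ``SUT2`` gene, with
  no close ortholog, is renamed past the highest number in either species:
  ``SUC28``.
- **STP** (hexose transporters): the grapevine ``HT`` symbols move under
  the *Arabidopsis* ``STP`` root, with the ``HT`` names kept as synonyms.
- **ERD6L**: the family root ``ERD6`` ends with a digit, so an ``L``
  (-like) is inserted before every designator; the unnamed *Arabidopsis*
  members transfer no symbols.
- **CCD**: a duplicated pair in the ``CCD1`` subgroup is differentiated by
  letters (the historical ``CCD1`` and obsolete ``NCED1`` stay as synonyms
  of ``CCD1a``); ``CCD8b`` is kept although no *Arabidopsis* gene belongs
  to its subgroup.
- **STS** (trihydroxystilbene synthases): no *Arabidopsis* members at all;
  genes are numbered by tree traversal, never by chromosome position.

The random generators mirror these conditions for property tests: two
species, bootstrap supports uniform on [50, 100], duplications injected at
a configurable rate.  All generators are pure functions of their seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .phylo import FamilyRegistry, GeneTree, LeafInfo, NamingOptions
from .registry import Registry, SynonymEntry, SynonymKind, SynonymNote
from .locus_id import ObjectType

__all__ = [
    "VITIS",
    "ARABIDOPSIS",
    "Scenario",
    "build_worked_scenarios",
    "random_family",
    "random_registry",
    "write_scenario",
]

VITIS = "Vitis_vinifera"
ARABIDOPSIS = "Arabidopsis_thaliana"


@dataclass
class Scenario:
    """One naming scenario: inputs plus the expected engine output.

    ``expected_proposals`` maps gene id to (symbol, synonym names); empty
    for randomized scenarios whose outcome is checked by properties only.
    """

    name: str
    tree: GeneTree
    family: FamilyRegistry
    focal_species: str = VITIS
    reference_species: str = ARABIDOPSIS
    options: NamingOptions = field(default_factory=NamingOptions)
    prior_names: Dict[str, List[str]] = field(default_factory=dict)
    expected_proposals: Dict[str, Tuple[str, Tuple[str, ...]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        genes = {info.gene_id for info in self.tree.leaf_infos()}
        unknown = set(self.expected_proposals) - genes
        if unknown:
            raise ValueError(f"expected proposals for absent genes: {unknown}")


def _leaf(species: str, gene_id: str, symbol: str = "",
          phenotype: bool = False) -> str:
    return LeafInfo(species, gene_id, symbol or None, phenotype).label()


def _eil_scenario() -> Scenario:
    vv = _leaf(VITIS, "VIT06s0009g01380")
    vv2a = _leaf(VITIS, "VIT03s0038g01600")
    vv2b = _leaf(VITIS, "VIT11s0016g03910")
    vv4 = _leaf(VITIS, "VIT00s0357g00120")
    ein3 = _leaf(ARABIDOPSIS, "AT3G20770", "EIN3", phenotype=True)
    eil1 = _leaf(ARABIDOPSIS, "AT2G27050", "EIL1")
    eil2 = _leaf(ARABIDOPSIS, "AT5G21120", "EIL2")
    slim1 = _leaf(ARABIDOPSIS, "AT1G73730", "SLIM1", phenotype=True)
    u1 = _leaf(ARABIDOPSIS, "AT5G65100")
    u2 = _leaf(ARABIDOPSIS, "AT5G25350")
    newick = (f"((({vv},{ein3})95,({vv2a},{vv2b},{eil2})90)80,"
              f"({vv4},{u1},{u2},{slim1},{eil1})85);")
    family = FamilyRegistry.from_symbols(
        "EIL",
        {VITIS: [], ARABIDOPSIS: ["EIN3", "EIL1", "EIL2", "SLIM1"]},
        full_name_root="ethylene insensitive 3-like",
    )
    return Scenario(
        name="EIL",
        tree=GeneTree.from_newick(newick),
        family=family,
        prior_names={},
        expected_proposals={
            "VIT06s0009g01380": ("EIL3", ("EIN3",)),
            "VIT03s0038g01600": ("EIL2a", ()),
            "VIT11s0016g03910": ("EIL2b", ()),
            "VIT00s0357g00120": ("EIL4", ()),
        },
    )


def _suc_scenario() -> Scenario:
    suc11 = _leaf(VITIS, "VIT18s0076g00250", "SUC11")
    suc12 = _leaf(VITIS, "VIT01s0026g01960", "SUC12")
    suc27 = _leaf(VITIS, "VIT18s0001g08210", "SUC27")
    sut2 = _leaf(VITIS, "VIT11s0016g00700", "SUT2")
    at1 = _leaf(ARABIDOPSIS, "AT1G71880", "SUC1")
    newick = f"((({suc11},{at1})90,({suc12},{suc27})75)80,{sut2});"
    family = FamilyRegistry.from_symbols(
        "SUC",
        {VITIS: ["SUC11", "SUC12", "SUC27"],
         ARABIDOPSIS: [f"SUC{i}" for i in range(1, 10)]},
        full_name_root="sucrose transporter",
    )
    options = NamingOptions(extra_prior_names={
        "VIT18s0076g00250": (SynonymEntry("SUT1", SynonymKind.SYMBOL,
                                          SynonymNote.OBSOLETE,
                                          "earlier classification"),),
    })
    return Scenario(
        name="SUC",
        tree=GeneTree.from_newick(newick),
        family=family,
        options=options,
        prior_names={"VIT18s0076g00250": ["SUC11", "SUT1"],
                     "VIT01s0026g01960": ["SUC12"],
                     "VIT18s0001g08210": ["SUC27"],
                     "VIT11s0016g00700": ["SUT2"]},
        expected_proposals={
            "VIT18s0076g00250": ("SUC11", ("SUT1",)),
            "VIT01s0026g01960": ("SUC12", ()),
            "VIT18s0001g08210": ("SUC27", ()),
            "VIT11s0016g00700": ("SUC28", ("SUT2",)),
        },
    )


def _stp_scenario() -> Scenario:
    ht1 = _leaf(VITIS, "VIT00s0181g00010", "HT1")
    ht2 = _leaf(VITIS, "VIT18s0001g05570", "HT2")
    stp1 = _leaf(ARABIDOPSIS, "AT1G11260", "STP1")
    stp13 = _leaf(ARABIDOPSIS, "AT5G26340", "STP13")
    # the 65-support branch collapses at the default 70% threshold
    newick = f"(({ht1},{stp1})90,({ht2},{stp13})65);"
    family = FamilyRegistry.from_symbols(
        "STP",
        {VITIS: [], ARABIDOPSIS: ["STP1", "STP13"]},
        full_name_root="sugar transport protein",
    )
    return Scenario(
        name="STP",
        tree=GeneTree.from_newick(newick),
        family=family,
        prior_names={"VIT00s0181g00010": ["HT1"],
                     "VIT18s0001g05570": ["HT2"]},
        expected_proposals={
            "VIT00s0181g00010": ("STP1", ("HT1",)),
            "VIT18s0001g05570": ("STP14", ("HT2",)),
        },
    )


def _erd6_scenario() -> Scenario:
    e1 = _leaf(VITIS, "VIT05s0020g03140")
    e2 = _leaf(VITIS, "VIT14s0068g00960")
    e3 = _leaf(VITIS, "VIT07s0005g02730")
    u1 = _leaf(ARABIDOPSIS, "AT1G08930")  # ERD6 itself carries no symbol here
    u2 = _leaf(ARABIDOPSIS, "AT1G75220")
    newick = f"(({e1},{u1})80,({e2},({e3},{u2})75)90);"
    family = FamilyRegistry.from_symbols(
        "ERD6",
        {VITIS: [], ARABIDOPSIS: []},
        full_name_root="early response to dehydration 6-like transporter",
    )
    return Scenario(
        name="ERD6L",
        tree=GeneTree.from_newick(newick),
        family=family,
        expected_proposals={
            "VIT05s0020g03140": ("ERD6L1", ()),
            "VIT14s0068g00960": ("ERD6L2", ()),
            "VIT07s0005g02730": ("ERD6L3", ()),
        },
    )


def _ccd_scenario() -> Scenario:
    ccd1a = _leaf(VITIS, "VIT13s0064g00810", "CCD1")
    ccd1b = _leaf(VITIS, "VIT13s0064g00840")
    at_ccd1 = _leaf(ARABIDOPSIS, "AT3G63520", "CCD1")
    ccd8b = _leaf(VITIS, "VIT04s0008g03510", "CCD8b")
    newick = f"(({ccd1a},{ccd1b},{at_ccd1})95,{ccd8b});"
    family = FamilyRegistry.from_symbols(
        "CCD",
        {VITIS: ["CCD1", "CCD8b"], ARABIDOPSIS: ["CCD1"]},
        full_name_root="carotenoid cleavage dioxygenase",
    )
    options = NamingOptions(extra_prior_names={
        "VIT13s0064g00810": (SynonymEntry("NCED1", SynonymKind.SYMBOL,
                                          SynonymNote.OBSOLETE,
                                          "gene shows CCD-like function"),),
    })
    return Scenario(
        name="CCD",
        tree=GeneTree.from_newick(newick),
        family=family,
        options=options,
        prior_names={"VIT13s0064g00810": ["CCD1", "NCED1"],
                     "VIT04s0008g03510": ["CCD8b"]},
        expected_proposals={
            "VIT13s0064g00810": ("CCD1a", ("CCD1", "NCED1")),
            "VIT13s0064g00840": ("CCD1b", ()),
            "VIT04s0008g03510": ("CCD8b", ()),
        },
    )


def _sts_scenario() -> Scenario:
    # gene ids deliberately out of chromosome order: numbering must follow
    # the tree, not the genome coordinates
    s1 = _leaf(VITIS, "VIT16s0100g00910")
    s2 = _leaf(VITIS, "VIT10s0042g00920")
    s3 = _leaf(VITIS, "VIT16s0100g01130")
    s4 = _leaf(VITIS, "VIT10s0042g00870")
    newick = f"(({s1},{s2})85,({s3},{s4})90);"
    family = FamilyRegistry.from_symbols(
        "STS", {VITIS: [], ARABIDOPSIS: []},
        full_name_root="trihydroxystilbene synthase",
    )
    return Scenario(
        name="STS",
        tree=GeneTree.from_newick(newick),
        family=family,
        expected_proposals={
            "VIT16s0100g00910": ("STS1", ()),
            "VIT10s0042g00920": ("STS2", ()),
            "VIT16s0100g01130": ("STS3", ()),
            "VIT10s0042g00870": ("STS4", ()),
        },
    )


def build_worked_scenarios() -> List[Scenario]:
    """The six worked scenarios, rebuilt from scratch (no downloads)."""
    return [
        _eil_scenario(),
        _suc_scenario(),
        _stp_scenario(),
        _erd6_scenario(),
        _ccd_scenario(),
        _sts_scenario(),
    ]


# ---------------------------------------------------------------------------
# randomized instances


def random_family(seed: int, n_focal: int, n_reference: int,
                  duplication_rate: float = 0.0) -> Scenario:
    """A reproducible two-species family scenario.

    The backbone pairs focal and reference genes into speciation cherries
    (leftover genes of the larger side attach singly above); duplications
    then replace a leaf with a same-species cherry at the given rate.
    Bootstrap supports are uniform integers on [50, 100].
    """
    if n_focal < 1 or n_reference < 1:
        raise ValueError("need at least one gene per species")
    rng = random.Random(seed)
    counters = {"F": 0, "R": 0}

    def new_leaf(side: str) -> dict:
        counters[side] += 1
        species = VITIS if side == "F" else ARABIDOPSIS
        gene = f"{'Vv' if side == 'F' else 'At'}{counters[side]}"
        symbol = f"FAM{counters[side]}" if side == "R" else ""
        return {"leaf": _leaf(species, gene, symbol)}

    def join(a: dict, b: dict) -> dict:
        return {"children": [a, b], "support": rng.randint(50, 100)}

    n_pairs = min(n_focal, n_reference)
    subtrees = [join(new_leaf("F"), new_leaf("R")) for _ in range(n_pairs)]
    extras = (["F"] * (n_focal - n_pairs)) + (["R"] * (n_reference - n_pairs))
    tree = subtrees[0]
    for sub in subtrees[1:]:
        tree = join(tree, sub)
    for side in extras:
        tree = join(tree, new_leaf(side))

    def inject_duplications(node: dict) -> dict:
        if "leaf" in node:
            if rng.random() < duplication_rate:
                species = node["leaf"].split("|")[0]
                side = "F" if species == VITIS else "R"
                return join(node, new_leaf(side))
            return node
        node["children"] = [inject_duplications(c) for c in node["children"]]
        return node

    if duplication_rate > 0:
        tree = inject_duplications(tree)

    def render(node: dict) -> str:
        if "leaf" in node:
            return node["leaf"]
        inner = ",".join(render(c) for c in node["children"])
        return f"({inner}){node['support']}"

    family = FamilyRegistry.from_symbols(
        "FAM",
        {VITIS: [],
         ARABIDOPSIS: [f"FAM{i + 1}" for i in range(counters["R"])]},
    )
    return Scenario(
        name=f"random-{seed}",
        tree=GeneTree.from_newick(render(tree) + ";"),
        family=family,
    )


def random_registry(seed: int,
                    genes_per_chromosome: Sequence[int]) -> Registry:
    """A registry populated through ``create_gene`` only, in a seeded
    interleaved chromosome order, so every lifecycle invariant holds by
    construction and the event log replays exactly."""
    if any(n < 0 or n > 99999 for n in genes_per_chromosome):
        raise ValueError("per-chromosome counts must lie in [0, 99999]")
    rng = random.Random(seed)
    pending = [chrom for chrom, count in enumerate(genes_per_chromosome)
               for _ in range(count)]
    rng.shuffle(pending)
    reg = Registry()
    for chrom in pending:
        reg.create_gene(chrom, ObjectType.GENE, actor="generator")
    return reg


def write_scenario(scenario: Scenario, directory: str | Path) -> None:
    """Serialize a scenario as newick + TSV + JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "tree.nwk").write_text(scenario.tree.to_newick() + "\n")
    lines = ["species\tsymbol"]
    for species in sorted(scenario.family.used_designators):
        for symbol in sorted(scenario.family.used_symbols(species)):
            lines.append(f"{species}\t{symbol}")
    for symbol in sorted(scenario.family.phenotype_symbols):
        lines.append(f"-\t{symbol}")
    (directory / "family.tsv").write_text("\n".join(lines) + "\n")
    meta = {
        "name": scenario.name,
        "family_root": scenario.family.family_root,
        "focal_species": scenario.focal_species,
        "reference_species": scenario.reference_species,
        "prior_names": scenario.prior_names,
        "expected_proposals": {
            gene: {"symbol": symbol, "synonyms": list(synonyms)}
            for gene, (symbol, synonyms) in scenario.expected_proposals.items()
        },
    }
    (directory / "expected.json").write_text(json.dumps(meta, indent=2) + "\n")
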