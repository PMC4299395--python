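"""Phylogeny-driven gene-symbol proposals.

Given a support-labelled gene tree containing grapevine (focal) and
*Arabidopsis* (reference) family members, this module

1. collapses poorly supported branches (bootstrap below 70% by default)
   into polytomies, because weaker values imply a misleading hierarchy;
2. classifies ortholog relations between the two species with the
   species-overlap method (an internal node is a duplication iff two of its
   child subtrees share a species; focal/reference leaves whose last common
   ancestor is a speciation node are orthologs) — a deliberate lightweight
   stand-in for a full tree-reconciliation pipeline, adequate on curated
   family trees;
3. proposes one symbol per grapevine gene by a fixed rule order, keeping
   every displaced historical name as a synonym.

Symbol grammar: a 2-5 letter family root plus a 1-3 digit locus designator,
optionally differentiated by a trailing lowercase letter; when the root
itself ends in a digit (``ERD6``) an ``L`` (for "-like") is inserted between
root and designator.  The ``Vvi`` species prefix is display-only and never
part of the stored symbol.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy

from .registry import SynonymEntry, SynonymKind, SynonymNote

__all__ = [
    "PhyloError",
    "SymbolCollisionError",
    "DesignatorCapacityError",
    "LeafInfo",
    "GeneTree",
    "RelationClass",
    "OrthologyRelation",
    "FamilyRegistry",
    "SymbolProposal",
    "NamingOptions",
    "collapse_weak_branches",
    "infer_orthology",
    "next_available_designator",
    "propose_symbol",
    "apply_family_naming",
    "validate_symbol",
    "parse_symbol",
]

DEFAULT_SUPPORT_THRESHOLD = 70.0


class PhyloError(Exception):
    """Base class for naming-engine errors."""


class SymbolCollisionError(PhyloError):
    """Two genes in one family run would receive the same symbol."""


class DesignatorCapacityError(PhyloError):
    """The 3-digit locus-designator space (999) is exhausted."""


# ---------------------------------------------------------------------------
# gene trees


@dataclass(frozen=True)
class LeafInfo:
    """Per-leaf annotation: species, gene identifier, any existing symbol,
    and whether that symbol refers to a mutant phenotype."""

    species: str
    gene_id: str
    existing_symbol: Optional[str] = None
    phenotype_named: bool = False

    def label(self, delimiter: str = "|") -> str:
        parts = [self.species, self.gene_id, self.existing_symbol or ""]
        if self.phenotype_named:
            parts.append("P")
        return delimiter.join(parts)

    @classmethod
    def from_label(cls, label: str, delimiter: str = "|") -> "LeafInfo":
        parts = label.split(delimiter)
        if len(parts) < 2:
            raise PhyloError(
                f"leaf label {label!r} must be "
                f"species{delimiter}gene_id[{delimiter}symbol[{delimiter}P]]"
            )
        species, gene_id = parts[0], parts[1]
        symbol = parts[2] if len(parts) > 2 and parts[2] else None
        phenotype = len(parts) > 3 and "P" in parts[3]
        return cls(species, gene_id, symbol, phenotype)


class GeneTree:
    """A rooted gene tree with bootstrap supports on internal nodes.

    Wraps a :mod:`dendropy` tree; supports are read either from internal
    node labels (``(...)95``) or from ``[&support=95]`` comments.  Leaves
    carry :class:`LeafInfo` parsed from delimited labels.
    """

    def __init__(self, tree: dendropy.Tree, delimiter: str = "|") -> None:
        self._tree = tree
        self.delimiter = delimiter
        self._annotate()

    def _annotate(self) -> None:
        for node in self._tree:
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                node.leaf_info = LeafInfo.from_label(label, self.delimiter)
                node.support = None
            else:
                node.leaf_info = None
                node.support = _extract_support(node)

    @classmethod
    def from_newick(cls, text: str, delimiter: str = "|") -> "GeneTree":
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls(tree, delimiter)

    def to_newick(self) -> str:
        for node in self._tree:
            if node.is_leaf():
                label = node.leaf_info.label(self.delimiter)
                if node.taxon is not None:
                    node.taxon.label = label
                else:
                    node.label = label
            else:
                node.label = (_format_support(node.support)
                              if node.support is not None else None)
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def clone(self) -> "GeneTree":
        return GeneTree.from_newick(self.to_newick(), self.delimiter)

    # -- traversal helpers ----------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def leaves(self) -> List[dendropy.Node]:
        return [n for n in self._tree.leaf_node_iter()]

    def leaf_infos(self) -> List[LeafInfo]:
        return [n.leaf_info for n in self.leaves()]

    def species_set(self) -> Set[str]:
        return {info.species for info in self.leaf_infos()}

    def leaf_by_gene_id(self, gene_id: str) -> dendropy.Node:
        for node in self.leaves():
            if node.leaf_info.gene_id == gene_id:
                return node
        raise PhyloError(f"gene {gene_id!r} not found in tree")

    def ordered_leaves(self) -> List[dendropy.Node]:
        """Leaves in traversal order: depth-first, children left-to-right
        as written in the input newick.  This is the order a curator sees
        in the drawn tree, and it is what numbers a family when no other
        rule decides (identical inputs always give identical output)."""
        out: List[dendropy.Node] = []

        def walk(node: dendropy.Node) -> None:
            if node.is_leaf():
                out.append(node)
                return
            for child in node.child_nodes():
                walk(child)

        walk(self.root)
        return out


def _extract_support(node: dendropy.Node) -> Optional[float]:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            pass
    value = node.annotations.get_value("support")  # [&support=..] comments
    if value is not None:
        return float(value)
    for comment in getattr(node, "comments", []) or []:
        m = re.search(r"&?support\s*=\s*([0-9.]+)", comment)
        if m:
            return float(m.group(1))
    return None


def _format_support(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


def collapse_weak_branches(tree: GeneTree,
                           support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
                           ) -> GeneTree:
    """Contract every internal edge whose support is *below* the threshold
    (strict: support exactly at the threshold is retained), promoting the
    node's children into the parent and forming polytomies.  Leaves and
    their annotations are never touched; unsupported (unlabelled) internal
    edges are retained.  Idempotent."""
    out = tree.clone()
    for node in list(out._tree.postorder_node_iter()):
        if node.is_leaf() or node.parent_node is None:
            continue
        if node.support is not None and node.support < support_threshold:
            parent = node.parent_node
            children = list(node.child_nodes())
            parent.remove_child(node)
            for child in children:
                parent.add_child(child)
    return out


# ---------------------------------------------------------------------------
# orthology


class RelationClass(enum.Enum):
    ONE2ONE = "one2one"
    ONE2MANY = "one2many"
    MANY2MANY = "many2many"
    NONE = "none"


@dataclass(frozen=True)
class OrthologyRelation:
    """Ortholog classification of one focal gene against the reference
    species: the reference genes it descends from a speciation node with,
    and the relation class implied by the bipartite ortholog graph."""

    vitis_gene: str
    reference_genes: Tuple[str, ...]
    relation_class: RelationClass

    def __post_init__(self) -> None:
        if (self.relation_class is RelationClass.ONE2ONE
                and len(self.reference_genes) != 1):
            raise ValueError("one2one requires exactly one reference gene")


def _species_sets(tree: GeneTree) -> Dict[dendropy.Node, Set[str]]:
    sets: Dict[dendropy.Node, Set[str]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = {node.leaf_info.species}
        else:
            sets[node] = set().union(*(sets[c] for c in node.child_nodes()))
    return sets


def duplication_nodes(tree: GeneTree) -> Set[dendropy.Node]:
    """Internal nodes labelled duplication by species overlap: at least two
    child subtrees share at least one species."""
    sets = _species_sets(tree)
    dups: Set[dendropy.Node] = set()
    for node in tree._tree.preorder_internal_node_iter():
        children = node.child_nodes()
        seen: Set[str] = set()
        for child in children:
            if sets[child] & seen:
                dups.add(node)
                break
            seen |= sets[child]
    return dups


def _lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
    ancestors = set()
    node = a
    while node is not None:
        ancestors.add(node)
        node = node.parent_node
    node = b
    while node is not None:
        if node in ancestors:
            return node
        node = node.parent_node
    raise PhyloError("nodes share no ancestor")


def infer_orthology(tree: GeneTree, focal_species: str,
                    reference_species: str) -> List[OrthologyRelation]:
    """Classify every focal-species gene against the reference species.

    A focal and a reference leaf are orthologs iff their last common
    ancestor is a speciation node under the species-overlap labelling.  The
    relation class counts both sides of the bipartite ortholog graph: a
    focal gene with one ortholog that is itself orthologous to several
    focal genes is one2many, not one2one.
    """
    focal = [n for n in tree.ordered_leaves()
             if n.leaf_info.species == focal_species]
    reference = [n for n in tree.ordered_leaves()
                 if n.leaf_info.species == reference_species]
    if not focal:
        raise PhyloError(f"no {focal_species!r} leaves in tree")
    dups = duplication_nodes(tree)

    orthologs: Dict[str, List[str]] = {n.leaf_info.gene_id: [] for n in focal}
    co_orthologs: Dict[str, Set[str]] = {}
    for f in focal:
        for r in reference:
            if _lca(f, r) not in dups:
                orthologs[f.leaf_info.gene_id].append(r.leaf_info.gene_id)
                co_orthologs.setdefault(r.leaf_info.gene_id,
                                        set()).add(f.leaf_info.gene_id)

    relations = []
    for f in focal:
        gid = f.leaf_info.gene_id
        refs = tuple(orthologs[gid])
        if not refs:
            klass = RelationClass.NONE
        else:
            partners = set().union(*(co_orthologs[r] for r in refs))
            if len(refs) == 1 and len(partners) == 1:
                klass = RelationClass.ONE2ONE
            elif len(refs) > 1 and len(partners) > 1:
                klass = RelationClass.MANY2MANY
            else:
                klass = RelationClass.ONE2MANY
        relations.append(OrthologyRelation(gid, refs, klass))
    return relations


# ---------------------------------------------------------------------------
# family registries and symbols


@dataclass
class FamilyRegistry:
    """Symbols in use within one gene family, per species.

    ``used_designators`` maps species to the set of (number, letter) pairs
    already taken; ``phenotype_symbols`` holds off-root names (``EIN3``,
    ``SLIM1``) that occupy no designator.  When ``family_root`` ends with a
    digit, an ``L`` is inserted before the designator unless
    ``insert_like_letter`` overrides the default.
    """

    family_root: str
    used_designators: Dict[str, Set[Tuple[int, str]]] = field(default_factory=dict)
    phenotype_symbols: Set[str] = field(default_factory=set)
    full_name_root: Optional[str] = None
    insert_like_letter: Optional[bool] = None

    @property
    def root_ends_with_digit(self) -> bool:
        return self.family_root[-1].isdigit()

    @property
    def effective_root(self) -> str:
        insert = (self.root_ends_with_digit
                  if self.insert_like_letter is None
                  else self.insert_like_letter)
        return self.family_root + ("L" if insert else "")

    def make_symbol(self, number: int, letter: str = "") -> str:
        return f"{self.effective_root}{number}{letter}"

    def parse(self, symbol: str) -> Optional[Tuple[int, str]]:
        return parse_symbol(symbol, self.family_root,
                            like_letter=self.effective_root != self.family_root)

    def register(self, species: str, number: int, letter: str = "") -> None:
        self.used_designators.setdefault(species, set()).add((number, letter))

    def used_symbols(self, species: str) -> Set[str]:
        return {self.make_symbol(n, l)
                for n, l in self.used_designators.get(species, set())}

    @classmethod
    def from_symbols(cls, family_root: str,
                     symbols_by_species: Mapping[str, Iterable[str]],
                     **kwargs) -> "FamilyRegistry":
        """Build a registry from per-species symbol lists; symbols that do
        not fit the root+designator grammar are recorded as off-root
        (phenotype-style) names."""
        reg = cls(family_root, **kwargs)
        for species, symbols in symbols_by_species.items():
            reg.used_designators.setdefault(species, set())
            for symbol in symbols:
                parsed = reg.parse(symbol)
                if parsed is not None:
                    reg.used_designators[species].add(parsed)
                else:
                    reg.phenotype_symbols.add(symbol)
        return reg


def parse_symbol(symbol: str, root: str,
                 like_letter: bool = False) -> Optional[Tuple[int, str]]:
    """Parse ``symbol`` as root(+L)+designator(+letter); None if it does
    not fit the family's format."""
    effective = root + ("L" if like_letter else "")
    for candidate in ({effective, root} if like_letter else {root}):
        m = re.fullmatch(re.escape(candidate) + r"(\d{1,3})([a-z]?)",
                         symbol, flags=re.IGNORECASE)
        if m:
            return int(m.group(1)), m.group(2).lower()
    return None


def next_available_designator(family: FamilyRegistry,
                              species_scope: Iterable[str]) -> int:
    """The next free family number: one higher than the highest designator
    used in *any* species of the scope (1 when the family is empty)."""
    scope = list(species_scope)
    if not scope:
        raise PhyloError("species scope must be non-empty")
    numbers = [n for sp in scope
               for n, _ in family.used_designators.get(sp, set())]
    nxt = max(numbers, default=0) + 1
    if nxt > 999:
        raise DesignatorCapacityError(
            f"family {family.family_root!r} exhausted its 3-digit "
            "designator space"
        )
    return nxt


_SYMBOL_SHAPE = re.compile(
    r"^(?P<root>[A-Za-z][A-Za-z0-9]*?)(?P<digits>\d{1,4})?(?P<letter>[a-z]?)$"
)


def validate_symbol(symbol: str) -> List[str]:
    """Check a symbol against the naming convention; returns violations.

    The root should have 2-5 letters, the locus designator 1-3 digits, and
    the symbol must not embed a species prefix (``vv``/``Vv`` collides with
    *Vibrio vulnificus*; ``Vvi`` is reserved for display only).
    """
    violations: List[str] = []
    if not symbol:
        return ["empty symbol"]
    if symbol.lower().startswith("vv"):
        violations.append(
            "species prefix embedded in symbol (vv/Vv is locked by Vibrio "
            "vulnificus; Vvi is display-only)"
        )
    m = _SYMBOL_SHAPE.match(symbol)
    if m is None:
        violations.append(f"symbol {symbol!r} does not fit "
                          "<root letters><1-3 digits>[letter]")
        return violations
    n_root_letters = sum(c.isalpha() for c in m.group("root"))
    if n_root_letters < 2:
        violations.append(f"root of {symbol!r} has fewer than 2 letters")
    elif n_root_letters > 5:
        violations.append(f"root of {symbol!r} has more than 5 letters")
    digits = m.group("digits")
    if digits is None:
        violations.append(f"{symbol!r} lacks a 1-3 digit locus designator")
    elif len(digits) > 3:
        violations.append(f"locus designator of {symbol!r} exceeds 3 digits")
    return violations


# ---------------------------------------------------------------------------
# the proposal engine


@dataclass
class NamingOptions:
    """Knobs of the proposal engine.

    ``phenotype_names`` supplies grapevine mutant-phenotype names that take
    absolute precedence; ``extra_prior_names`` lists additional historical
    names (beyond the leaf's own symbol) to fold in as synonyms;
    ``display_prefix`` (e.g. ``Vvi``) affects rendering only.
    """

    phenotype_names: Mapping[str, str] = field(default_factory=dict)
    extra_prior_names: Mapping[str, Sequence[SynonymEntry]] = field(
        default_factory=dict)
    display_prefix: Optional[str] = None


@dataclass
class SymbolProposal:
    """The engine's verdict for one grapevine gene: the recommended symbol,
    its full name, every synonym to register, the ordered rule trail that
    produced it, and any convention violations (attached, never blocking)."""

    gene_id: str
    symbol: str
    full_name: str
    synonyms_to_register: List[SynonymEntry] = field(default_factory=list)
    display_prefix: Optional[str] = None
    rationale: List[str] = field(default_factory=list)
    violations: List[str] = field(default_factory=list)

    @property
    def designator(self) -> Optional[int]:
        m = re.search(r"(\d{1,3})[a-z]?$", self.symbol)
        return int(m.group(1)) if m else None

    @property
    def display_symbol(self) -> str:
        return f"{self.display_prefix or ''}{self.symbol}"


class FamilyNamer:
    """One naming run over a collapsed family tree.

    Rule order (first match wins; the trail is recorded per proposal):

    - ``phenotype-name``: a grapevine mutant-phenotype name is supplied for
      the gene — it wins outright.
    - ``equal-distance-letters``: two or more grapevine genes equally
      distant from a single numbered reference gene share its designator and
      are differentiated by letters (a, b, ...) in traversal order.
    - ``keep-historical``: the gene's existing symbol already fits the
      family format and is free — keep it.
    - ``adopt-ortholog-symbol``: a one2one ortholog of a reference gene
      whose symbol fits the family format adopts that symbol.
    - ``off-root-ortholog``: a one2one ortholog of a phenotype-named /
      off-root reference gene takes the next free family number; the
      off-root name becomes a synonym.
    - ``next-number``: anything else (one2many, many2many, no ortholog, or
      a family absent from the reference species) takes the next free
      number — which, with genes processed in traversal order, numbers a
      reference-free family by the tree, never by chromosome position.
    """

    def __init__(self, family: FamilyRegistry, tree: GeneTree,
                 relations: Sequence[OrthologyRelation],
                 focal_species: str, reference_species: str,
                 options: Optional[NamingOptions] = None) -> None:
        self.family = family
        self.tree = tree
        self.focal_species = focal_species
        self.reference_species = reference_species
        self.options = options or NamingOptions()
        self.relations = {r.vitis_gene: r for r in relations}
        self.scope = (focal_species, reference_species)
        # collisions are tracked within the focal species only: a grapevine
        # gene adopting its Arabidopsis ortholog's symbol is the goal, not
        # a clash — the species is disambiguated outside the symbol
        self._claimed: Set[str] = {
            s.upper() for s in self.family.used_symbols(focal_species)
        }
        # a gene's own historical symbol is not a collision against itself;
        # if two genes share one, the first keeper claims it back
        for leaf in tree.ordered_leaves():
            info = leaf.leaf_info
            if info.species == focal_species and info.existing_symbol:
                parsed = self.family.parse(info.existing_symbol)
                if parsed is not None:
                    self._claimed.discard(
                        self.family.make_symbol(*parsed).upper())
        self._groups = self._equal_distance_groups()

    # -- helpers ---------------------------------------------------------

    def _ref_leaf(self, gene_id: str) -> dendropy.Node:
        return self.tree.leaf_by_gene_id(gene_id)

    def _nearest_reference(self, leaf: dendropy.Node
                           ) -> Optional[Tuple[dendropy.Node, int]]:
        """Unique topologically nearest reference leaf and its distance,
        or None on a tie or when no reference leaf exists."""
        best: List[dendropy.Node] = []
        best_dist = 0
        for other in self.tree.ordered_leaves():
            if other.leaf_info.species != self.reference_species:
                continue
            d = _topological_distance(leaf, other)
            if not best or d < best_dist:
                best, best_dist = [other], d
            elif d == best_dist:
                best.append(other)
        return (best[0], best_dist) if len(best) == 1 else None

    def _equal_distance_groups(self) -> Dict[str, Tuple[str, int, str]]:
        """Map gene_id -> (shared reference gene, designator, suffix letter)
        for grapevine genes that sit as siblings under one node, adjacent
        to the same single numbered reference gene.

        "Equally distant" is taken structurally: the members share a parent
        (polytomy or cherry) and their unique nearest reference leaf is the
        same gene at most three edges away — i.e. in the same polytomy or
        attached just outside the cherry.  Remote relatives that merely
        share a nearest reference gene keep their own designators.
        """
        by_parent: Dict[Tuple[dendropy.Node, str], List[dendropy.Node]] = {}
        ref_number: Dict[str, int] = {}
        for leaf in self.tree.ordered_leaves():
            if leaf.leaf_info.species != self.focal_species:
                continue
            relation = self.relations.get(leaf.leaf_info.gene_id)
            if relation is not None and relation.relation_class is RelationClass.ONE2ONE:
                continue  # resolved genes are never letter-suffixed
            nearest = self._nearest_reference(leaf)
            if nearest is None:
                continue
            ref_leaf, dist = nearest
            if dist > 3 or ref_leaf.leaf_info.existing_symbol is None:
                continue
            parsed = self.family.parse(ref_leaf.leaf_info.existing_symbol)
            if parsed is None or parsed[1]:
                continue  # off-root or already letter-suffixed reference
            prior = leaf.leaf_info.existing_symbol
            if prior is not None:
                own = self.family.parse(prior)
                if own is not None and own[0] != parsed[0]:
                    continue  # historically numbered outside this subgroup
            ref_number[ref_leaf.leaf_info.gene_id] = parsed[0]
            by_parent.setdefault(
                (leaf.parent_node, ref_leaf.leaf_info.gene_id), []
            ).append(leaf)

        # letters run per reference gene, in traversal order, across all
        # sibling groups that point at it — designators stay unique even
        # when several polytomies surround the same reference gene
        groups: Dict[str, Tuple[str, int, str]] = {}
        letter_index: Dict[str, int] = {}
        for leaf in self.tree.ordered_leaves():
            gid = leaf.leaf_info.gene_id
            for (parent, ref_gene), members in by_parent.items():
                if leaf in members and len(members) >= 2:
                    i = letter_index.get(ref_gene, 0)
                    letter_index[ref_gene] = i + 1
                    groups[gid] = (ref_gene, ref_number[ref_gene],
                                   chr(ord("a") + i))
        return groups

    def _claim(self, symbol: str, gene_id: str) -> None:
        if symbol.upper() in self._claimed:
            raise SymbolCollisionError(
                f"symbol {symbol!r} proposed for {gene_id} is already in "
                f"use within the {self.family.family_root} family"
            )
        self._claimed.add(symbol.upper())

    def _full_name(self, symbol: str) -> str:
        if self.family.full_name_root:
            suffix = symbol[len(self.family.effective_root):]
            return f"{self.family.full_name_root} {suffix}".strip()
        return symbol

    def _finish(self, gene_id: str, symbol: str, rationale: List[str],
                synonyms: List[SynonymEntry]) -> SymbolProposal:
        self._claim(symbol, gene_id)
        parsed = self.family.parse(symbol)
        if parsed is not None:
            self.family.register(self.focal_species, *parsed)
        leaf = self.tree.leaf_by_gene_id(gene_id)
        prior = leaf.leaf_info.existing_symbol
        if prior and prior.upper() != symbol.upper():
            if not any(s.name.lower() == prior.lower() for s in synonyms):
                synonyms.append(SynonymEntry(prior, SynonymKind.SYMBOL,
                                             SynonymNote.OBSOLETE,
                                             "superseded by renaming"))
        for extra in self.options.extra_prior_names.get(gene_id, ()):
            if not any(s.key() == extra.key() for s in synonyms):
                synonyms.append(extra)
        return SymbolProposal(
            gene_id=gene_id,
            symbol=symbol,
            full_name=self._full_name(symbol),
            synonyms_to_register=synonyms,
            display_prefix=self.options.display_prefix,
            rationale=rationale,
            violations=validate_symbol(symbol),
        )

    # -- the rules -------------------------------------------------------

    def propose(self, gene_id: str) -> SymbolProposal:
        rationale: List[str] = []
        synonyms: List[SynonymEntry] = []
        leaf = self.tree.leaf_by_gene_id(gene_id)
        if leaf.leaf_info.species != self.focal_species:
            raise PhyloError(f"{gene_id} is not a {self.focal_species} gene")

        phenotype = self.options.phenotype_names.get(gene_id)
        if phenotype:
            rationale.append("phenotype-name")
            return self._finish(gene_id, phenotype, rationale, synonyms)

        if gene_id in self._groups:
            ref_gene, number, letter = self._groups[gene_id]
            rationale.append("equal-distance-letters")
            symbol = self.family.make_symbol(number, letter)
            return self._finish(gene_id, symbol, rationale, synonyms)

        prior = leaf.leaf_info.existing_symbol
        if prior is not None:
            parsed = self.family.parse(prior)
            if parsed is not None:
                canonical = self.family.make_symbol(*parsed)
                if canonical.upper() not in self._claimed:
                    rationale.append("keep-historical")
                    return self._finish(gene_id, canonical, rationale, synonyms)

        relation = self.relations.get(
            gene_id, OrthologyRelation(gene_id, (), RelationClass.NONE))
        if relation.relation_class is RelationClass.ONE2ONE:
            ref_info = self._ref_leaf(relation.reference_genes[0]).leaf_info
            ref_symbol = ref_info.existing_symbol
            parsed = self.family.parse(ref_symbol) if ref_symbol else None
            if parsed is not None:
                symbol = self.family.make_symbol(*parsed)
                if symbol.upper() not in self._claimed:
                    rationale.append("adopt-ortholog-symbol")
                    return self._finish(gene_id, symbol, rationale, synonyms)
                rationale.append("ortholog-symbol-taken")
            elif ref_symbol:
                rationale.append("off-root-ortholog")
                synonyms.append(SynonymEntry(
                    ref_symbol, SynonymKind.SYMBOL, SynonymNote.NONE,
                    "one2one ortholog named off the family root"))

        if not self.family.used_designators.get(self.reference_species):
            rationale.append("no-reference-members")
        rationale.append("next-number")
        number = next_available_designator(self.family, self.scope)
        symbol = self.family.make_symbol(number)
        return self._finish(gene_id, symbol, rationale, synonyms)

    def propose_all(self) -> List[SymbolProposal]:
        proposals = []
        for leaf in self.tree.ordered_leaves():
            if leaf.leaf_info.species == self.focal_species:
                proposals.append(self.propose(leaf.leaf_info.gene_id))
        return proposals


def _topological_distance(a: dendropy.Node, b: dendropy.Node) -> int:
    lca = _lca(a, b)
    d = 0
    for node in (a, b):
        while node is not lca:
            node = node.parent_node
            d += 1
    return d


def propose_symbol(family: FamilyRegistry, gene_id: str,
                   relations: Sequence[OrthologyRelation], tree: GeneTree,
                   focal_species: str, reference_species: str,
                   options: Optional[NamingOptions] = None) -> SymbolProposal:
    """Propose a symbol for a single gene (see :class:`FamilyNamer` for the
    rule order)."""
    namer = FamilyNamer(family, tree, relations, focal_species,
                        reference_species, options)
    return namer.propose(gene_id)


def apply_family_naming(family: FamilyRegistry, tree: GeneTree,
                        relations: Sequence[OrthologyRelation],
                        focal_species: str, reference_species: str,
                        options: Optional[NamingOptions] = None,
                        ) -> List[SymbolProposal]:
    """Name every focal-species gene of a (collapsed) family tree, in
    deterministic traversal order, with mutually unique symbols."""
    namer = FamilyNamer(family, tree, relations, focal_species,
                        reference_species, options)
    return namer.propose_all()
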