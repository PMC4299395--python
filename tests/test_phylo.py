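import itertools
import random

import pytest

from vitinom.fixtures import ARABIDOPSIS, VITIS, random_family
from vitinom.phylo import (
    DesignatorCapacityError,
    FamilyRegistry,
    GeneTree,
    RelationClass,
    SymbolCollisionError,
    apply_family_naming,
    collapse_weak_branches,
    infer_orthology,
    next_available_designator,
    parse_symbol,
    propose_symbol,
    validate_symbol,
)


def leaf(species, gene, symbol=""):
    return f"{species}|{gene}|{symbol}"


class TestTreeIO:
    def test_supports_from_internal_labels(self):
        tree = GeneTree.from_newick(
            f"(({leaf(VITIS,'Vv1')},{leaf(ARABIDOPSIS,'At1')})95,"
            f"{leaf(VITIS,'Vv2')});")
        supports = [n.support for n in tree._tree.preorder_internal_node_iter()]
        assert 95.0 in supports

    def test_supports_from_comment_dialect(self):
        tree = GeneTree.from_newick(
            f"(({leaf(VITIS,'Vv1')},{leaf(ARABIDOPSIS,'At1')})[&support=88],"
            f"{leaf(VITIS,'Vv2')});")
        supports = [n.support for n in tree._tree.preorder_internal_node_iter()]
        assert 88.0 in supports

    def test_leaf_metadata_round_trip(self):
        text = (f"(({leaf(VITIS,'Vv1','EIL3')},"
                f"{ARABIDOPSIS}|AT3G20770|EIN3|P)95,{leaf(VITIS,'Vv2')});")
        tree = GeneTree.from_newick(text)
        reparsed = GeneTree.from_newick(tree.to_newick())
        infos = {i.gene_id: i for i in reparsed.leaf_infos()}
        assert infos["Vv1"].existing_symbol == "EIL3"
        assert infos["AT3G20770"].phenotype_named
        assert infos["Vv2"].existing_symbol is None


class TestCollapse:
    def balanced_tree(self, s1, s2, s3):
        """Three internal edges under the root carrying supports s1..s3."""
        leaves = [leaf(VITIS, f"Vv{i}") for i in range(1, 5)]
        at = [leaf(ARABIDOPSIS, f"At{i}") for i in range(1, 5)]
        return GeneTree.from_newick(
            f"((({leaves[0]},{at[0]}){s2},({leaves[1]},{at[1]}){s3}){s1},"
            f"({leaves[2]},{at[2]})90,({leaves[3]},{at[3]})90);")

    @staticmethod
    def n_internal(tree):
        return sum(1 for _ in tree._tree.preorder_internal_node_iter())

    def test_below_threshold_collapsed(self):
        tree = self.balanced_tree(65, 90, 90)
        collapsed = collapse_weak_branches(tree)
        assert self.n_internal(collapsed) == self.n_internal(tree) - 1

    def test_at_threshold_retained(self):
        tree = self.balanced_tree(70, 90, 90)
        collapsed = collapse_weak_branches(tree)
        assert self.n_internal(collapsed) == self.n_internal(tree)

    def test_69_collapsed_70_retained(self):
        for support, kept in [(69, False), (70, True)]:
            tree = self.balanced_tree(support, 90, 90)
            collapsed = collapse_weak_branches(tree)
            expected = self.n_internal(tree) - (0 if kept else 1)
            assert self.n_internal(collapsed) == expected

    def test_all_strong_tree_unchanged_and_idempotent(self):
        tree = self.balanced_tree(90, 95, 100)
        once = collapse_weak_branches(tree)
        twice = collapse_weak_branches(once)
        assert once.to_newick() == tree.to_newick()
        assert twice.to_newick() == once.to_newick()

    @pytest.mark.parametrize("seed", range(40))
    def test_leaf_set_preserved_on_random_trees(self, seed):
        scenario = random_family(seed, n_focal=1 + seed % 6,
                                 n_reference=1 + (seed * 7) % 5,
                                 duplication_rate=0.3)
        before = {i.gene_id for i in scenario.tree.leaf_infos()}
        collapsed = collapse_weak_branches(scenario.tree)
        after = {i.gene_id for i in collapsed.leaf_infos()}
        assert before == after
        again = collapse_weak_branches(collapsed)
        assert again.to_newick() == collapsed.to_newick()

    def test_raising_threshold_never_resolves(self):
        tree = self.balanced_tree(65, 72, 90)
        at_70 = collapse_weak_branches(tree, 70)
        at_80 = collapse_weak_branches(tree, 80)
        assert self.n_internal(at_80) <= self.n_internal(at_70)


# ---------------------------------------------------------------------------
# brute-force species-overlap oracle on nested-tuple trees


def tuple_leaves(t):
    if isinstance(t, str):
        return [t]
    return [x for child in t for x in tuple_leaves(child)]


def tuple_species(t):
    return {name[0] for name in tuple_leaves(t)}


def oracle_orthologs(tree):
    """Orthologous (focal, reference) leaf pairs by direct enumeration:
    find every pair's meeting node by descending from the root and test the
    species-overlap duplication rule on that node independently."""

    def contains(t, x):
        return x in tuple_leaves(t)

    def lca(t, a, b):
        if not isinstance(t, str):
            for child in t:
                if contains(child, a) and contains(child, b):
                    return lca(child, a, b)
        return t

    pairs = set()
    leaves = tuple_leaves(tree)
    focal = [x for x in leaves if x.startswith("F")]
    reference = [x for x in leaves if x.startswith("R")]
    for f in focal:
        for r in reference:
            node = lca(tree, f, r)
            seen = set()
            duplication = False
            for child in (node if not isinstance(node, str) else ()):
                sub = {name[0] for name in tuple_leaves(child)}
                if sub & seen:
                    duplication = True
                seen |= sub
            if not duplication:
                pairs.add((f, r))
    return pairs


def oracle_relations(tree):
    pairs = oracle_orthologs(tree)
    focal = [x for x in tuple_leaves(tree) if x.startswith("F")]
    out = {}
    for f in focal:
        refs = {r for (ff, r) in pairs if ff == f}
        if not refs:
            out[f] = ("none", frozenset())
            continue
        partners = {ff for (ff, r) in pairs if r in refs}
        if len(refs) == 1 and len(partners) == 1:
            klass = "one2one"
        elif len(refs) > 1 and len(partners) > 1:
            klass = "many2many"
        else:
            klass = "one2many"
        out[f] = (klass, frozenset(refs))
    return out


def tuple_to_newick(t):
    def render(node):
        if isinstance(node, str):
            species = VITIS if node.startswith("F") else ARABIDOPSIS
            return f"{species}|{node}"
        return "(" + ",".join(render(c) for c in node) + ")100"
    return render(t) + ";"


def all_binary_topologies(leaves):
    if len(leaves) == 1:
        yield leaves[0]
        return
    for sub in all_binary_topologies(leaves[1:]):
        yield from _insert(sub, leaves[0])


def _insert(tree, new_leaf):
    yield (new_leaf, tree)
    if not isinstance(tree, str):
        left, right = tree
        for t in _insert(left, new_leaf):
            yield (t, right)
        for t in _insert(right, new_leaf):
            yield (left, t)


def species_assignments(n):
    for combo in itertools.product("FR", repeat=n):
        if "F" in combo:
            yield combo


class TestOrthology:
    def test_minimal_speciation_cherry(self):
        tree = GeneTree.from_newick(
            f"({leaf(VITIS,'Vv1')},{leaf(ARABIDOPSIS,'At1')})95;")
        (rel,) = infer_orthology(tree, VITIS, ARABIDOPSIS)
        assert rel.relation_class is RelationClass.ONE2ONE
        assert rel.reference_genes == ("At1",)

    def test_within_vitis_duplication_gives_one2many(self):
        tree = GeneTree.from_newick(
            f"((({leaf(VITIS,'Vv1')},{leaf(VITIS,'Vv2')})90,"
            f"{leaf(ARABIDOPSIS,'At1')})95);")
        relations = {r.vitis_gene: r for r in
                     infer_orthology(tree, VITIS, ARABIDOPSIS)}
        for gene in ("Vv1", "Vv2"):
            assert relations[gene].relation_class is RelationClass.ONE2MANY
            assert relations[gene].reference_genes == ("At1",)

    def test_polytomy_members_are_not_one2one(self):
        tree = GeneTree.from_newick(
            f"(({leaf(VITIS,'Vv1')},{leaf(VITIS,'Vv2')},"
            f"{leaf(ARABIDOPSIS,'At_EIL2','EIL2')})90,"
            f"{leaf(ARABIDOPSIS,'At1')});")
        relations = {r.vitis_gene: r for r in
                     infer_orthology(tree, VITIS, ARABIDOPSIS)}
        for gene in ("Vv1", "Vv2"):
            assert relations[gene].relation_class is not RelationClass.ONE2ONE

    def test_no_reference_leaves_gives_none(self):
        tree = GeneTree.from_newick(
            f"({leaf(VITIS,'Vv1')},{leaf(VITIS,'Vv2')})90;")
        for rel in infer_orthology(tree, VITIS, ARABIDOPSIS):
            assert rel.relation_class is RelationClass.NONE

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5])
    def test_matches_bruteforce_oracle_exhaustively(self, n_leaves):
        """Species-overlap orthology equals the direct pairwise oracle on
        every rooted binary topology and species assignment of small trees."""
        base = [f"L{i}" for i in range(n_leaves)]
        for topology in all_binary_topologies(base):
            for assignment in species_assignments(n_leaves):
                renames = {f"L{i}": f"{assignment[i]}{i}"
                           for i in range(n_leaves)}

                def rename(t):
                    if isinstance(t, str):
                        return renames[t]
                    return tuple(rename(c) for c in t)

                tree_t = rename(topology)
                expected = oracle_relations(tree_t)
                got = infer_orthology(GeneTree.from_newick(
                    tuple_to_newick(tree_t)), VITIS, ARABIDOPSIS)
                observed = {r.vitis_gene:
                            (r.relation_class.value,
                             frozenset(r.reference_genes)) for r in got}
                assert observed == expected

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_oracle_on_random_larger_trees(self, seed):
        rng = random.Random(seed)
        n_leaves = rng.choice([6, 7])
        base = [f"L{i}" for i in range(n_leaves)]
        topologies = list(itertools.islice(all_binary_topologies(base), 500))
        topology = rng.choice(topologies)
        assignment = rng.choice(list(species_assignments(n_leaves)))
        renames = {f"L{i}": f"{assignment[i]}{i}" for i in range(n_leaves)}

        def rename(t):
            if isinstance(t, str):
                return renames[t]
            return tuple(rename(c) for c in t)

        tree_t = rename(topology)
        expected = oracle_relations(tree_t)
        got = infer_orthology(GeneTree.from_newick(tuple_to_newick(tree_t)),
                              VITIS, ARABIDOPSIS)
        observed = {r.vitis_gene: (r.relation_class.value,
                                   frozenset(r.reference_genes)) for r in got}
        assert observed == expected


class TestDesignators:
    @pytest.mark.parametrize("vitis,arabidopsis,expected", [
        ([], [1, 2], 3),
        ([], [1, 2, 3], 4),
        ([11, 12, 27], list(range(1, 10)), 28),
        ([], [], 1),
    ])
    def test_next_available(self, vitis, arabidopsis, expected):
        family = FamilyRegistry.from_symbols(
            "SUC",
            {VITIS: [f"SUC{n}" for n in vitis],
             ARABIDOPSIS: [f"SUC{n}" for n in arabidopsis]})
        assert next_available_designator(family,
                                         [VITIS, ARABIDOPSIS]) == expected

    def test_capacity(self):
        family = FamilyRegistry.from_symbols("SUC", {VITIS: ["SUC999"]})
        with pytest.raises(DesignatorCapacityError):
            next_available_designator(family, [VITIS])

    def test_parse_symbol_with_like_letter(self):
        assert parse_symbol("ERD6L3", "ERD6", like_letter=True) == (3, "")
        assert parse_symbol("ERD6L3b", "ERD6", like_letter=True) == (3, "b")
        assert parse_symbol("EIL2a", "EIL") == (2, "a")
        assert parse_symbol("EIN3", "EIL") is None


class TestValidateSymbol:
    @pytest.mark.parametrize("symbol,n_violations", [
        ("ADH1", 0),
        ("EIL2a", 0),
        ("ERD6L12", 0),
        ("A1", 1),           # root too short
        ("TRANSPORT1234", 2),  # root too long + designator too long
        ("VvADH1", 1),       # embedded species prefix
        ("EIN", 1),          # no designator
    ])
    def test_violation_counts(self, symbol, n_violations):
        assert len(validate_symbol(symbol)) == n_violations


class TestProposals:
    def eil_tree(self):
        return GeneTree.from_newick(
            f"(({leaf(VITIS,'Vv1')},"
            f"{ARABIDOPSIS}|AT3G20770|EIN3|P)95,"
            f"({leaf(VITIS,'Vv2')},{leaf(ARABIDOPSIS,'At_EIL1','EIL1')})90);")

    def eil_family(self):
        return FamilyRegistry.from_symbols(
            "EIL", {VITIS: [],
                    ARABIDOPSIS: ["EIN3", "EIL1", "EIL2", "SLIM1"]})

    def test_off_root_ortholog_gets_next_number_and_synonym(self):
        tree = self.eil_tree()
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        proposal = propose_symbol(self.eil_family(), "Vv1", relations, tree,
                                  VITIS, ARABIDOPSIS)
        assert proposal.symbol == "EIL3"
        assert [s.name for s in proposal.synonyms_to_register] == ["EIN3"]
        assert "off-root-ortholog" in proposal.rationale

    def test_on_root_ortholog_symbol_adopted(self):
        tree = self.eil_tree()
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        proposal = propose_symbol(self.eil_family(), "Vv2", relations, tree,
                                  VITIS, ARABIDOPSIS)
        assert proposal.symbol == "EIL1"
        assert "adopt-ortholog-symbol" in proposal.rationale

    def test_letter_suffixes_follow_traversal_order(self):
        tree = GeneTree.from_newick(
            f"(({leaf(VITIS,'VvB')},{leaf(VITIS,'VvA')},"
            f"{leaf(ARABIDOPSIS,'At_EIL2','EIL2')})90,"
            f"{leaf(ARABIDOPSIS,'At_EIL1','EIL1')});")
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        proposals = apply_family_naming(self.eil_family(), tree, relations,
                                        VITIS, ARABIDOPSIS)
        symbols = {p.gene_id: p.symbol for p in proposals}
        # VvB is written first in the newick, so it takes the first letter
        assert symbols == {"VvB": "EIL2a", "VvA": "EIL2b"}

    def test_like_letter_inserted_for_digit_root(self):
        family = FamilyRegistry.from_symbols("ERD6", {VITIS: [],
                                                      ARABIDOPSIS: []})
        tree = GeneTree.from_newick(
            f"({leaf(VITIS,'Vv1')},{leaf(VITIS,'Vv2')})90;")
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        proposals = apply_family_naming(family, tree, relations,
                                        VITIS, ARABIDOPSIS)
        assert [p.symbol for p in proposals] == ["ERD6L1", "ERD6L2"]

    def test_phenotype_name_wins(self):
        tree = self.eil_tree()
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        from vitinom.phylo import NamingOptions
        options = NamingOptions(phenotype_names={"Vv1": "GLAB1"})
        proposal = propose_symbol(self.eil_family(), "Vv1", relations, tree,
                                  VITIS, ARABIDOPSIS, options)
        assert proposal.symbol == "GLAB1"
        assert proposal.rationale == ["phenotype-name"]

    def test_duplicate_historical_symbol_collides_to_next_number(self):
        # two genes both claiming STS2 historically: the first keeps it,
        # the second is renamed with the historical name as synonym
        family = FamilyRegistry.from_symbols("STS", {VITIS: ["STS2"],
                                                     ARABIDOPSIS: []})
        tree = GeneTree.from_newick(
            f"({leaf(VITIS,'Vv1','STS2')},{leaf(VITIS,'Vv2','STS2')})90;")
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        proposals = apply_family_naming(family, tree, relations,
                                        VITIS, ARABIDOPSIS)
        symbols = [p.symbol for p in proposals]
        assert symbols[0] == "STS2"
        assert symbols[1] == "STS3"
        assert [s.name for s in proposals[1].synonyms_to_register] == ["STS2"]

    @pytest.mark.parametrize("seed", range(60))
    def test_no_duplicate_symbols_on_random_families(self, seed):
        scenario = random_family(seed, n_focal=2 + seed % 5,
                                 n_reference=1 + seed % 4,
                                 duplication_rate=0.4)
        tree = collapse_weak_branches(scenario.tree)
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        proposals = apply_family_naming(scenario.family, tree, relations,
                                        VITIS, ARABIDOPSIS, scenario.options)
        symbols = [p.symbol for p in proposals]
        assert len(symbols) == len(set(symbols))

    def test_designator_conservation_after_each_acceptance(self):
        scenario = random_family(5, n_focal=4, n_reference=2,
                                 duplication_rate=0.5)
        tree = collapse_weak_branches(scenario.tree)
        relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
        family = scenario.family
        proposals = apply_family_naming(family, tree, relations,
                                        VITIS, ARABIDOPSIS)
        top = max(p.designator for p in proposals
                  if p.designator is not None)
        reference_top = max(
            (n for n, _ in family.used_designators.get(ARABIDOPSIS, set())),
            default=0)
        assert next_available_designator(family, [VITIS, ARABIDOPSIS]) == \
            max(top, reference_top) + 1

    def test_determinism(self):
        scenario = random_family(9, 4, 3, 0.3)
        results = []
        for _ in range(2):
            tree = collapse_weak_branches(scenario.tree)
            relations = infer_orthology(tree, VITIS, ARABIDOPSIS)
            family = FamilyRegistry.from_symbols(
                "FAM", {VITIS: [],
                        ARABIDOPSIS: sorted(
                            scenario.family.used_symbols(ARABIDOPSIS))})
            proposals = apply_family_naming(family, tree, relations,
                                            VITIS, ARABIDOPSIS)
            results.append([(p.gene_id, p.symbol) for p in proposals])
        assert results[0] == results[1]
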