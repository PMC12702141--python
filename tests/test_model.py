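import random

import pytest

from glycan_babel.errors import GlycanParseError
from glycan_babel.fixtures import random_tree
from glycan_babel.model import (
    GlycanTree,
    Linkage,
    Monosaccharide,
    Node,
    check_brackets,
    longest_chain_length,
    parse_iupac_to_tree,
    tree_to_string,
    trees_equal,
)


class TestMonosaccharide:
    @pytest.mark.parametrize(
        "token",
        ["Glc", "Gal", "GlcNAc", "Neu5Ac", "Neu5Gc", "Kdn", "Fuc", "L-Gal",
         "Galf", "Gal6S", "GlcNAc6S", "GalOS", "Man6P", "Gal3Me", "Hex",
         "HexNAc", "dHex", "Mon", "IdoA", "D-Fuc"],
    )
    def test_token_round_trip(self, token):
        assert Monosaccharide.from_token(token).to_token() == token

    def test_default_enantiomer_is_dropped(self):
        assert Monosaccharide.from_token("D-Glc").to_token() == "Glc"
        assert Monosaccharide.from_token("L-Fuc").to_token() == "Fuc"

    def test_unknown_token_raises(self):
        with pytest.raises(GlycanParseError, match="Xyzzy"):
            Monosaccharide.from_token("Xyzzy")

    def test_duplicate_modification_positions_rejected(self):
        with pytest.raises(GlycanParseError):
            Monosaccharide("Gal", modifications=((6, "S"), (6, "P")))

    def test_modifications_sorted_integers_before_unknown(self):
        m = Monosaccharide("Gal", modifications=((None, "S"), (4, "P"), (3, "Me")))
        assert m.modifications == ((3, "Me"), (4, "P"), (None, "S"))
        assert m.to_token() == "Gal3Me4POS"

    def test_blocked_positions_hexose(self):
        # anomeric C1 and ring-oxygen C5
        assert Monosaccharide.from_token("Glc").blocked_positions() == {1, 5}
        assert Monosaccharide.from_token("GlcNAc").blocked_positions() == {1, 2, 5}

    def test_blocked_positions_sialic(self):
        assert Monosaccharide.from_token("Neu5Ac").blocked_positions() == {1, 2, 3, 5, 6}


class TestLinkage:
    def test_round_trip(self):
        for s in ["b1-4", "a2-3", "?1-?", "a1-3/4", "b1-?"]:
            assert str(Linkage.from_string(s)) == s

    def test_wildcard_must_be_singleton(self):
        with pytest.raises(GlycanParseError):
            Linkage("a", "1", ("?", 3))

    def test_acceptor_rank_orders_integers_before_wildcard(self):
        assert Linkage.from_string("a1-3").acceptor_rank() < Linkage.from_string(
            "a1-?"
        ).acceptor_rank()
        assert Linkage.from_string("a1-3/4").acceptor_rank() == (0, 3)


class TestParse:
    def test_lactose(self):
        t = parse_iupac_to_tree("Gal(b1-4)Glc")
        assert t.root.residue.base_name == "Glc"
        assert len(t.root.children) == 1
        child, link = t.root.children[0]
        assert child.residue.base_name == "Gal"
        assert (link.anomer, link.donor, link.acceptors) == ("b", "1", (4,))

    def test_single_residue(self):
        t = parse_iupac_to_tree("Glc")
        assert t.root.residue.base_name == "Glc"
        assert t.root.children == []
        assert t.floating == []

    def test_floating_part(self):
        t = parse_iupac_to_tree("{Neu5Ac(a2-?)}Gal(b1-4)Glc")
        assert len(t.floating) == 1
        part, link = t.floating[0]
        assert part.residue.base_name == "Neu5Ac"
        assert link.acceptors == ("?",)
        # round-trip
        assert tree_to_string(t) == "{Neu5Ac(a2-?)}Gal(b1-4)Glc"

    def test_branches_become_siblings(self):
        t = parse_iupac_to_tree("Man(a1-3)[Man(a1-6)]Man")
        assert len(t.root.children) == 2
        accs = [l.acceptors for _, l in t.root.children]
        assert accs == [(3,), (6,)]

    def test_unbalanced_brackets_error_names_index(self):
        with pytest.raises(GlycanParseError, match="index"):
            parse_iupac_to_tree("Man(a1-3]Man")
        with pytest.raises(GlycanParseError, match="index"):
            check_brackets("Gal(b1-4")

    def test_unknown_token_error_names_token(self):
        with pytest.raises(GlycanParseError, match="Frob"):
            parse_iupac_to_tree("Frob(b1-4)Glc")

    def test_empty_string(self):
        with pytest.raises(GlycanParseError):
            parse_iupac_to_tree("  ")


class TestSerialize:
    def test_lactose_and_single(self):
        t = parse_iupac_to_tree("Gal(b1-4)Glc")
        assert tree_to_string(t) == "Gal(b1-4)Glc"
        assert tree_to_string(GlycanTree(Node(Monosaccharide("Man")))) == "Man"

    def test_sibling_order_preserved_verbatim(self):
        s = "Man(a1-6)[Man(a1-3)]Man"  # non-canonical order on purpose
        assert tree_to_string(parse_iupac_to_tree(s)) == s

    def test_cycle_raises(self):
        from glycan_babel.errors import StructureError

        a = Node(Monosaccharide("Glc"))
        b = Node(Monosaccharide("Gal"))
        a.children.append((b, Linkage("b", "1", (4,))))
        b.children.append((a, Linkage("b", "1", (4,))))
        with pytest.raises(StructureError):
            tree_to_string(GlycanTree(a))

    def test_round_trip_random_trees(self):
        rng = random.Random(99)
        for _ in range(300):
            t = random_tree(rng, max_nodes=15)
            s = tree_to_string(t)
            assert trees_equal(parse_iupac_to_tree(s), t)

    def test_serialized_brackets_balanced(self):
        rng = random.Random(5)
        for _ in range(100):
            check_brackets(tree_to_string(random_tree(rng)))


class TestLongestChain:
    def test_leaf_is_one(self):
        assert longest_chain_length(Node(Monosaccharide("Gal"))) == 1

    def test_lactose_root_is_two(self):
        t = parse_iupac_to_tree("Gal(b1-4)Glc")
        assert longest_chain_length(t.root) == 2

    @staticmethod
    def _all_paths(node, prefix=1):
        """Independent oracle: enumerate every root-to-leaf path length."""
        if not node.children:
            return [prefix]
        out = []
        for child, _ in node.children:
            out += TestLongestChain._all_paths(child, prefix + 1)
        return out

    def test_branched_subtree_matches_bruteforce(self):
        t = parse_iupac_to_tree("Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal")
        assert longest_chain_length(t.root) == 3
        assert longest_chain_length(t.root) == max(self._all_paths(t.root))

    def test_random_trees_match_bruteforce(self):
        rng = random.Random(7)
        for _ in range(100):
            t = random_tree(rng)
            assert longest_chain_length(t.root) == max(self._all_paths(t.root))
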