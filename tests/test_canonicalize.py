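import itertools
import random

from glycan_babel.canonicalize import (
    branch_key,
    canonical_string,
    canonicalize_branches,
)
from glycan_babel.fixtures import random_tree
from glycan_babel.model import (
    parse_iupac_to_tree,
    tree_to_string,
    trees_equal,
)


def canon(s: str) -> str:
    return canonical_string(parse_iupac_to_tree(s))


# -- independent oracle: brute-force label-isomorphism ----------------------


def _isomorphic(a, b) -> bool:
    if a.residue != b.residue or len(a.children) != len(b.children):
        return False
    if not a.children:
        return True
    for perm in itertools.permutations(b.children):
        if all(
            la == lb and _isomorphic(ca, cb)
            for (ca, la), (cb, lb) in zip(a.children, perm)
        ):
            return True
    return False


def _permute_siblings(node, rng):
    rng.shuffle(node.children)
    for child, _ in node.children:
        _permute_siblings(child, rng)


def _all_sibling_orders(node):
    """Every tree obtainable by permuting siblings (small trees only)."""
    child_variants = []
    for child, link in node.children:
        child_variants.append([(c, link) for c in _all_sibling_orders(child)])
    results = []
    for combo in itertools.product(*child_variants):
        for perm in itertools.permutations(combo):
            from glycan_babel.model import Node

            results.append(Node(node.residue, list(perm)))
    return results or [node]


class TestBranchKey:
    def test_leaf_key_components(self):
        t = parse_iupac_to_tree("Neu5Ac(a2-3)Gal")
        child, link = t.root.children[0]
        key = branch_key(child, link)
        assert key[0] == -1  # chain length 1, negated for ascending sort
        assert key[1] == (0, 3)
        assert key[2] == "Neu5Ac"

    def test_chain_key(self):
        t = parse_iupac_to_tree("Gal(b1-3)GalNAc(b1-4)Gal")
        child, link = t.root.children[0]
        assert branch_key(child, link)[:2] == (-2, (0, 4))

    def test_isomorphic_branches_share_keys(self):
        t = parse_iupac_to_tree("Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)]Man")
        (c1, l1), (c2, l2) = t.root.children
        assert branch_key(c1, l1) == branch_key(c2, l2)


class TestCanonicalOrdering:
    def test_man_3_before_man_6(self):
        assert canon("Man(a1-6)[Man(a1-3)]Man") == "Man(a1-3)[Man(a1-6)]Man"

    def test_integer_before_wildcard(self):
        assert canon("Man(a1-?)[Man(a1-3)]Man") == "Man(a1-3)[Man(a1-?)]Man"

    def test_longest_chain_wins(self):
        assert canon("Neu5Ac(a2-3)[Gal(b1-3)GalNAc(b1-4)]Gal(b1-4)Glc") == (
            "Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc"
        )

    def test_m5_by_hand(self):
        # the two-Man arm continues the chain; equal-length children tie on 3<6
        scrambled = "Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        assert canon(scrambled) == (
            "Man(a1-3)[Man(a1-6)]Man(a1-6)[Man(a1-3)]Man(b1-4)GlcNAc(b1-4)GlcNAc"
        )

    def test_narrow_ambiguity_ranks_by_minimum(self):
        assert canon("Gal(b1-3/4)[Man(a1-2)]Glc") == "Man(a1-2)[Gal(b1-3/4)]Glc"
        assert canon("Man(a1-6)[Gal(b1-3/4)]Glc") == "Gal(b1-3/4)[Man(a1-6)]Glc"

    def test_alphabetic_tiebreak_on_leaf_labels(self):
        assert canon("Man(a1-3)[Gal(a1-3)]Glc") == "Gal(a1-3)[Man(a1-3)]Glc"

    def test_no_branches_untouched(self):
        assert canon("Gal(b1-4)Glc") == "Gal(b1-4)Glc"

    def test_floating_parts_sorted_alphabetically(self):
        s = "{Neu5Ac(a2-?)}{Fuc(a1-?)}Gal(b1-4)Glc"
        assert canon(s) == "{Fuc(a1-?)}{Neu5Ac(a2-?)}Gal(b1-4)Glc"


class TestCanonicalProperties:
    def test_permutation_invariance_random(self, corpus):
        rng = random.Random(42)
        branched = [c.canonical for c in corpus if "[" in c.canonical][:20]
        assert len(branched) >= 10
        for s in branched:
            expected = canon(s)
            t0 = parse_iupac_to_tree(s)
            for _ in range(10):
                t = t0.copy()
                _permute_siblings(t.root, rng)
                assert canonical_string(t) == expected

    def test_permutation_invariance_exhaustive_small(self):
        from glycan_babel.model import GlycanTree

        samples = [
            "Man(a1-3)[Man(a1-6)]Man",
            "Gal(b1-3)[Fuc(a1-4)]GlcNAc",
            "GlcNAc(b1-2)[GlcNAc(b1-4)]Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man",
            "Man(a1-2)[Gal(a1-3)][Xyl(b1-4)]Glc",
        ]
        for s in samples:
            t = parse_iupac_to_tree(s)
            expected = canonical_string(t)
            variants = _all_sibling_orders(t.root)
            assert len(variants) >= 2
            for v in variants:
                assert canonical_string(GlycanTree(v.copy())) == expected

    def test_idempotence_projection(self, rng):
        for _ in range(100):
            t = random_tree(rng, 12)
            once = canonicalize_branches(t)
            twice = canonicalize_branches(once)
            assert tree_to_string(once) == tree_to_string(twice)

    def test_uniqueness_oracle_on_corpus(self, corpus):
        trees = []
        for case in corpus:
            if "{" in case.canonical:
                continue
            t = parse_iupac_to_tree(case.canonical)
            if sum(1 for _ in t.root.walk()) <= 12:
                trees.append((case.canonical, t))
        assert len(trees) >= 30
        for (sa, ta), (sb, tb) in itertools.combinations(trees, 2):
            iso = _isomorphic(ta.root, tb.root)
            same = canonical_string(ta) == canonical_string(tb)
            assert iso == same, (sa, sb)

    def test_stability_under_rebuild_order(self, rng):
        for _ in range(50):
            t = random_tree(rng, 10)
            expected = canonical_string(t)
            shuffled = t.copy()
            _permute_siblings(shuffled.root, rng)
            assert canonical_string(shuffled) == expected
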