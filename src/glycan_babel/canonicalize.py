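"""Deterministic branch ordering.

Every glycan gets exactly one serialized string: at each node, siblings are
sorted so that the branch with the longest chain of monosaccharides comes
first and continues the main chain, ties broken by the linkage position at
the branch point (lower integers first, integers strictly before ``?``),
then alphabetically by the minimum leaf label, walking down the branch
until a difference is found (realized here as the serialized subtree, which
is a strict extension of the leaf-label walk along the sorted child order).

Children are processed before parents (post-order), so each subtree is
already canonical when its key is computed.
"""

from __future__ import annotations

from .model import GlycanTree, Linkage, Node, longest_chain_length, tree_to_string


def _min_leaf_label(node: Node) -> str:
    if not node.children:
        return node.residue.to_token()
    return min(_min_leaf_label(c) for c, _ in node.children)


def _serialized(node: Node) -> str:
    return tree_to_string(GlycanTree(node.copy()))


def branch_key(child: Node, link: Linkage):
    """Total-order sort key for a sibling branch (ascending = first)."""
    return (
        -longest_chain_length(child),
        link.acceptor_rank(),
        _min_leaf_label(child),
        _serialized(child) + str(link),
    )


def _canon(node: Node) -> Node:
    kids = [(_canon(c), l) for c, l in node.children]
    kids.sort(key=lambda cl: branch_key(*cl))
    return Node(node.residue, kids)


def canonicalize_branches(t: GlycanTree) -> GlycanTree:
    """Return a copy of ``t`` with canonical sibling order everywhere.

    Floating parts are excluded from branch ordering and sorted
    alphabetically among themselves.
    """
    floats = [(_canon(n), l) for n, l in t.floating]
    floats.sort(key=lambda nl: _serialized(nl[0]) + str(nl[1]))
    return GlycanTree(_canon(t.root), floats)


def canonical_string(t: GlycanTree) -> str:
    """THE canonical IUPAC-condensed string of a glycan tree."""
    return tree_to_string(canonicalize_branches(t))
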