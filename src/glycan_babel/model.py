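"""Core glycan data model.

Glycans are rooted trees: the root is the reducing-end residue (the
rightmost token of an IUPAC-condensed string), edges point child -> parent
and are labeled with a :class:`Linkage`.  Residues with undetermined
attachment ("floating parts") hang off the tree and are serialized inside
curly brackets before the main chain.

This module owns the residue namespace table, the token grammar for
monosaccharides and linkages, and the bidirectional conversion between
IUPAC-condensed strings and trees.  Branch *ordering* is deliberately not
handled here (see :mod:`glycan_babel.canonicalize`): ``tree_to_string``
preserves sibling order verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .errors import GlycanParseError, StructureError

# ---------------------------------------------------------------------------
# residue namespace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueClass:
    """Static chemistry of one base-name token.

    ``default_enantiomer`` is the form implied when no D-/L- prefix is
    written; ``donor`` the anomeric carbon; ``carbons`` the backbone length;
    ``extra_blocked`` carbon positions that never carry a free acceptor
    hydroxyl (carboxyls, deoxy positions, native N-acyl groups ...).
    """

    default_enantiomer: str
    donor: int
    carbons: int
    extra_blocked: frozenset[int] = frozenset()


def _rc(en: str, donor: int, carbons: int, *blocked: int) -> ResidueClass:
    return ResidueClass(en, donor, carbons, frozenset(blocked))


#: Controlled namespace of base-name tokens.  Defaults follow common usage:
#: D + pyranose almost everywhere, L for Fuc/Rha/Ara/IdoA, anomeric carbon 2
#: for sialic and other ulosonic acids.
NAMESPACE: dict[str, ResidueClass] = {
    # hexoses
    "Glc": _rc("D", 1, 6),
    "Gal": _rc("D", 1, 6),
    "Man": _rc("D", 1, 6),
    "All": _rc("D", 1, 6),
    "Alt": _rc("D", 1, 6),
    "Gul": _rc("D", 1, 6),
    "Ido": _rc("D", 1, 6),
    "Tal": _rc("D", 1, 6),
    "Hex": _rc("D", 1, 6),
    # N-acetylhexosamines (C2 carries the acetamido group)
    "GlcNAc": _rc("D", 1, 6, 2),
    "GalNAc": _rc("D", 1, 6, 2),
    "ManNAc": _rc("D", 1, 6, 2),
    "AllNAc": _rc("D", 1, 6, 2),
    "HexNAc": _rc("D", 1, 6, 2),
    # hexosamines
    "GlcN": _rc("D", 1, 6, 2),
    "GalN": _rc("D", 1, 6, 2),
    "ManN": _rc("D", 1, 6, 2),
    "HexN": _rc("D", 1, 6, 2),
    # deoxyhexoses (C6 deoxy)
    "Fuc": _rc("L", 1, 6, 6),
    "Rha": _rc("L", 1, 6, 6),
    "Qui": _rc("D", 1, 6, 6),
    "dHex": _rc("D", 1, 6, 6),
    # pentoses
    "Xyl": _rc("D", 1, 5),
    "Rib": _rc("D", 1, 5),
    "Lyx": _rc("D", 1, 5),
    "Ara": _rc("L", 1, 5),
    "Pen": _rc("D", 1, 5),
    # uronic acids (C6 carboxyl)
    "GlcA": _rc("D", 1, 6, 6),
    "GalA": _rc("D", 1, 6, 6),
    "ManA": _rc("D", 1, 6, 6),
    "IdoA": _rc("L", 1, 6, 6),
    "HexA": _rc("D", 1, 6, 6),
    # sialic / ulosonic acids (C1 carboxyl, C3 deoxy, C5 N-acyl or blocked)
    "Neu5Ac": _rc("D", 2, 9, 1, 3, 5),
    "Neu5Gc": _rc("D", 2, 9, 1, 3, 5),
    "Neu": _rc("D", 2, 9, 1, 3, 5),
    "Kdn": _rc("D", 2, 9, 1, 3, 5),
    "Kdo": _rc("D", 2, 8, 1, 3),
    # ketoses
    "Fru": _rc("D", 2, 6, 1),
    "Sor": _rc("L", 2, 6, 1),
    "Tag": _rc("D", 2, 6, 1),
    "Psi": _rc("D", 2, 6, 1),
    # assorted
    "Api": _rc("D", 1, 5),
    "Mur": _rc("D", 1, 6, 2, 3),
    "MurNAc": _rc("D", 1, 6, 2, 3),
    "Bac": _rc("D", 1, 6, 2, 4, 6),
    "LDManHep": _rc("D", 1, 7),
    "DDManHep": _rc("D", 1, 7),
    # monosaccharide wildcard
    "Mon": _rc("D", 1, 9),
}

#: bases sorted longest-first for greedy token matching
_BASES_BY_LENGTH = sorted(NAMESPACE, key=len, reverse=True)

#: residues whose anomeric carbon is 2
SIALIC_BASES = frozenset(b for b, c in NAMESPACE.items() if c.donor == 2)

#: modification tag vocabulary (extensible superset, longest-first)
MOD_TAGS = ("PCho", "PEtn", "NAc", "Me", "Ac", "Am", "Fo", "Gc", "S", "P")

_MOD_RE = re.compile(r"([1-9]|O)?(%s)" % "|".join(MOD_TAGS))


def donor_default(base_name: str) -> str:
    """Implied anomeric carbon for a base token ('1', '2' or '?')."""
    cls = NAMESPACE.get(base_name)
    if cls is None:
        return "?"
    return str(cls.donor)


# ---------------------------------------------------------------------------
# Monosaccharide
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Monosaccharide:
    """One residue: base name, optional explicit enantiomer/ring, mods.

    ``enantiomer``/``ring`` are ``None`` when the default form is implied;
    a non-default form is carried explicitly (e.g. ``L-Gal``, ``Galf``).
    Modifications are (position, tag) pairs; ``None`` position means the
    carbon is unknown (serialized with the letter ``O`` before the tag).
    """

    base_name: str
    enantiomer: str | None = None
    ring: str | None = None
    modifications: tuple[tuple[int | None, str], ...] = ()
    unknown: bool = False

    def __post_init__(self):
        ints = [p for p, _ in self.modifications if p is not None]
        if len(ints) != len(set(ints)):
            raise GlycanParseError(
                f"duplicate modification position in {self.modifications!r}"
            )
        # keep modifications in canonical order: integers first, ascending
        ordered = tuple(
            sorted(self.modifications, key=lambda m: (m[0] is None, m[0] or 0, m[1]))
        )
        object.__setattr__(self, "modifications", ordered)

    # -- token conversion ---------------------------------------------------

    @classmethod
    def from_token(cls, token: str, strict: bool = True) -> "Monosaccharide":
        """Parse a condensed residue token like ``GlcNAc``, ``Gal6S``, ``L-Gal``."""
        original = token
        enantiomer = None
        if len(token) > 2 and token[0] in "DL" and token[1] == "-":
            enantiomer = token[0]
            token = token[2:]
        base = None
        for cand in _BASES_BY_LENGTH:
            if token.startswith(cand):
                base = cand
                token = token[len(cand):]
                break
        if base is None:
            if strict:
                raise GlycanParseError(f"unknown token: {original!r}")
            return cls(original, unknown=True)
        ring = None
        if token.startswith("f"):
            ring = "f"
            token = token[1:]
        mods: list[tuple[int | None, str]] = []
        while token:
            m = _MOD_RE.match(token)
            if not m:
                if strict:
                    raise GlycanParseError(f"unknown token: {original!r}")
                return cls(original, unknown=True)
            pos = m.group(1)
            mods.append((int(pos) if pos and pos != "O" else None, m.group(2)))
            token = token[m.end():]
        if enantiomer == NAMESPACE[base].default_enantiomer:
            enantiomer = None  # default form is implied, never written
        return cls(base, enantiomer, ring, tuple(mods))

    def to_token(self) -> str:
        if self.unknown:
            return self.base_name
        parts = []
        if self.enantiomer:
            parts.append(f"{self.enantiomer}-")
        parts.append(self.base_name)
        if self.ring == "f":
            parts.append("f")
        for pos, tag in self.modifications:
            parts.append(f"{pos if pos is not None else 'O'}{tag}")
        return "".join(parts)

    # -- chemistry ----------------------------------------------------------

    def blocked_positions(self) -> frozenset[int]:
        """Carbon positions that cannot act as a glycosidic acceptor."""
        blocked = {p for p, _ in self.modifications if p is not None}
        cls = NAMESPACE.get(self.base_name)
        if cls is None:
            return frozenset(blocked)
        blocked.add(cls.donor)  # anomeric carbon
        ring_span = 3 if self.ring == "f" else 4
        blocked.add(cls.donor + ring_span)  # carbon bearing the ring oxygen
        blocked |= cls.extra_blocked
        return frozenset(blocked)

    @property
    def max_carbon(self) -> int:
        cls = NAMESPACE.get(self.base_name)
        return cls.carbons if cls else 9

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_token()


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

_LINKAGE_RE = re.compile(r"^([ab?])([12?])-([1-9?](?:/[1-9])*)$")


@dataclass(frozen=True)
class Linkage:
    """Anomer + donor carbon + acceptor position(s).

    ``acceptors`` is an ordered tuple of ints; narrow ambiguity like 3/4 is
    a multi-member tuple, full uncertainty the singleton ``('?',)``.
    """

    anomer: str = "?"
    donor: str = "?"
    acceptors: tuple[int | str, ...] = ("?",)

    def __post_init__(self):
        if self.anomer not in ("a", "b", "?"):
            raise GlycanParseError(f"bad anomer {self.anomer!r}")
        if self.donor not in ("1", "2", "?"):
            raise GlycanParseError(f"bad donor carbon {self.donor!r}")
        if not self.acceptors:
            raise GlycanParseError("empty acceptor set")
        if "?" in self.acceptors and len(self.acceptors) != 1:
            raise GlycanParseError("'?' acceptor must be the only member")

    @classmethod
    def from_string(cls, s: str) -> "Linkage":
        m = _LINKAGE_RE.match(s)
        if not m:
            raise GlycanParseError(f"bad linkage: {s!r}")
        accs = tuple(
            "?" if a == "?" else int(a) for a in m.group(3).split("/")
        )
        return cls(m.group(1), m.group(2), accs)

    def acceptor_rank(self) -> tuple[int, int]:
        """Sort rank: integer positions by value, strictly before '?'."""
        ints = [a for a in self.acceptors if a != "?"]
        if ints:
            return (0, min(ints))
        return (1, 0)

    def __str__(self) -> str:
        return f"{self.anomer}{self.donor}-" + "/".join(str(a) for a in self.acceptors)


WILDCARD_LINKAGE = Linkage("?", "?", ("?",))


# ---------------------------------------------------------------------------
# GlycanTree
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """A residue with its children; each child carries its linkage to us."""

    residue: Monosaccharide
    children: list[tuple["Node", Linkage]] = field(default_factory=list)

    def copy(self) -> "Node":
        return Node(self.residue, [(c.copy(), l) for c, l in self.children])

    def walk(self):
        """Yield every node of the subtree, pre-order."""
        yield self
        for child, _ in self.children:
            yield from child.walk()


@dataclass
class GlycanTree:
    """Rooted glycan tree plus floating (uncertain-attachment) parts."""

    root: Node
    floating: list[tuple[Node, Linkage]] = field(default_factory=list)

    def copy(self) -> "GlycanTree":
        return GlycanTree(
            self.root.copy(), [(n.copy(), l) for n, l in self.floating]
        )

    def nodes(self):
        yield from self.root.walk()
        for part, _ in self.floating:
            yield from part.walk()

    def __len__(self) -> int:
        return sum(1 for _ in self.nodes())


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def check_brackets(s: str) -> None:
    """Raise GlycanParseError at the first unbalanced (), [] or {}."""
    pairs = {")": "(", "]": "[", "}": "{"}
    stack: list[tuple[str, int]] = []
    for i, ch in enumerate(s):
        if ch in "([{":
            stack.append((ch, i))
        elif ch in ")]}":
            if not stack or stack[-1][0] != pairs[ch]:
                raise GlycanParseError(f"unbalanced {ch!r} at index {i}")
            stack.pop()
    if stack:
        ch, i = stack[-1]
        raise GlycanParseError(f"unbalanced {ch!r} at index {i}")


_RESIDUE_CHARS = re.compile(r"[^()\[\]{}]+")


def _parse_chain(s: str, allow_bare_tail: bool = True) -> tuple[Node, Linkage | None]:
    """Parse one bracket-free-at-top-level chain into its root node.

    Returns (root, trailing_linkage); the trailing linkage is non-None when
    the chain ends with ``(...)`` (as branch and floating contents do).
    """
    waiting: list[tuple[Node, Linkage]] = []
    stack: list[list[tuple[Node, Linkage]]] = []
    i, n = 0, len(s)
    last: tuple[Node, Linkage] | None = None
    while i < n:
        ch = s[i]
        if ch == "[":
            stack.append(waiting)
            waiting = []
            last = None
            i += 1
        elif ch == "]":
            if last is None or waiting != [last]:
                raise GlycanParseError(
                    f"branch without linkage before index {i} in {s!r}"
                )
            branch = last
            waiting = stack.pop()
            waiting.append(branch)
            last = None
            i += 1
        else:
            m = _RESIDUE_CHARS.match(s, i)
            if not m:
                raise GlycanParseError(f"unexpected {ch!r} at index {i} in {s!r}")
            token = m.group(0)
            i = m.end()
            residue = Monosaccharide.from_token(token)
            node = Node(residue, waiting)
            waiting = []
            if i < n and s[i] == "(":
                j = s.index(")", i)
                link = Linkage.from_string(s[i + 1 : j])
                i = j + 1
                last = (node, link)
                waiting = [last]
            else:
                if i < n and s[i] != "]":
                    raise GlycanParseError(
                        f"residue {token!r} not followed by a linkage in {s!r}"
                    )
                if i >= n:
                    if stack:
                        raise GlycanParseError(f"unbalanced '[' in {s!r}")
                    return node, None
                last = None
    # chain ended with a linkage (floating/branch style)
    if stack or last is None or waiting != [last]:
        raise GlycanParseError(f"dangling linkage or bracket in {s!r}")
    if not allow_bare_tail:
        raise GlycanParseError(f"chain may not end with a linkage: {s!r}")
    return last[0], last[1]


def parse_iupac_to_tree(s: str) -> GlycanTree:
    """Parse a standardized IUPAC-condensed string into a GlycanTree.

    Pre-condition: the string already passed the common stem (balanced
    brackets, tokens in namespace, linkages fully parenthesized).
    """
    s = s.strip()
    if not s:
        raise GlycanParseError("empty glycan string")
    check_brackets(s)
    floating: list[tuple[Node, Linkage]] = []
    while s.startswith("{"):
        j = s.index("}")
        content = s[1:j]
        s = s[j + 1 :]
        node, link = _parse_chain(content)
        floating.append((node, link if link is not None else WILDCARD_LINKAGE))
    if not s:
        raise GlycanParseError("glycan has no main chain")
    root, trailing = _parse_chain(s)
    if trailing is not None:
        raise GlycanParseError(f"main chain ends with a dangling linkage: {s!r}")
    return GlycanTree(root, floating)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _serialize_node(node: Node, seen: set[int]) -> str:
    if id(node) in seen:
        raise StructureError("cycle detected in glycan graph")
    seen.add(id(node))
    parts = []
    if node.children:
        first, flink = node.children[0]
        parts.append(f"{_serialize_node(first, seen)}({flink})")
        for child, link in node.children[1:]:
            parts.append(f"[{_serialize_node(child, seen)}({link})]")
    parts.append(node.residue.to_token())
    return "".join(parts)


def tree_to_string(t: GlycanTree) -> str:
    """Serialize a tree; sibling order is preserved verbatim.

    Floating parts are emitted first, each in its own ``{...}``, sorted
    alphabetically (their relative order carries no meaning).
    """
    seen: set[int] = set()
    floats = sorted(
        f"{{{_serialize_node(n, seen)}({l})}}" for n, l in t.floating
    )
    return "".join(floats) + _serialize_node(t.root, seen)


# ---------------------------------------------------------------------------
# simple tree metrics
# ---------------------------------------------------------------------------


def longest_chain_length(node: Node) -> int:
    """1 + the longest monosaccharide chain among children (1 for a leaf)."""
    if not node.children:
        return 1
    return 1 + max(longest_chain_length(c) for c, _ in node.children)


def trees_equal(a: GlycanTree | Node, b: GlycanTree | Node) -> bool:
    """Structural equality including sibling order and all labels."""
    if isinstance(a, GlycanTree) != isinstance(b, GlycanTree):
        return False
    if isinstance(a, GlycanTree):
        if len(a.floating) != len(b.floating):
            return False
        fa = sorted(tree_to_string(GlycanTree(n)) + str(l) for n, l in a.floating)
        fb = sorted(tree_to_string(GlycanTree(n)) + str(l) for n, l in b.floating)
        if fa != fb:
            return False
        a, b = a.root, b.root
    if a.residue != b.residue or len(a.children) != len(b.children):
        return False
    return all(
        la == lb and trees_equal(ca, cb)
        for (ca, la), (cb, lb) in zip(a.children, b.children)
    )
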