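"""Fixture corpus and synthetic-data generators.

The corpus is generated programmatically: a curated list of canonical
IUPAC-condensed glycans is re-encoded into each supported nomenclature by
small, independent encoder functions (written from the published definition
of each format, *not* by inverting the parsers' code paths), plus seeded
IUPAC dialect variants.  Every (variant, kind) pair must canonicalize back
to its recorded canonical string — that property IS the corpus test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .detection import NomenclatureKind
from .errors import GlycanError
from .model import (
    GlycanTree,
    Linkage,
    Monosaccharide,
    Node,
    parse_iupac_to_tree,
)

# ---------------------------------------------------------------------------
# curated canonical glycans (written directly in canonical branch order)
# ---------------------------------------------------------------------------

CANONICAL_GLYCANS: tuple[str, ...] = (
    "Gal(b1-4)Glc",
    "Gal(b1-4)GlcNAc",
    "GalNAc(b1-4)GlcNAc",
    "GlcNAc(b1-4)GlcNAc",
    "GlcNAc(b1-4)GlcNAc(b1-4)GlcNAc",
    "GlcNAc(b1-4)GlcNAc(b1-4)GlcNAc(b1-4)GlcNAc",
    "Man(a1-3)[Man(a1-6)]Man",
    "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "Man(a1-3)[Man(a1-6)]Man(a1-6)[Man(a1-3)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "Man(a1-2)Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-6)]Man(a1-6)]"
    "Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "Neu5Ac(a2-3)Gal(b1-4)Glc",
    "Neu5Ac(a2-6)Gal(b1-4)Glc",
    "Neu5Gc(a2-3)Gal(b1-4)Glc",
    "Neu5Ac(a2-6)Gal(b1-4)GlcNAc",
    "Neu5Gc(a2-6)Gal(b1-4)GlcNAc",
    "Kdn(a2-3)Gal(b1-4)Glc",
    "Fuc(a1-2)Gal(b1-4)Glc",
    "Fuc(a1-3)[Gal(b1-4)]Glc",
    "Fuc(a1-3)[Gal(b1-4)]GlcNAc",
    "Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "Fuc(a1-2)Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "Fuc(a1-2)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc",
    "Neu5Ac(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc",
    "Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc",
    "Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
    "Fuc(a1-2)Gal(b1-3)GlcNAc(b1-3)Gal(b1-4)Glc",
    "Gal(b1-3)[Fuc(a1-4)]GlcNAc(b1-3)Gal(b1-4)Glc",
    "Fuc(a1-3)[Gal(b1-4)]GlcNAc(b1-3)Gal(b1-4)Glc",
    "Gal(b1-3)GlcNAc(b1-3)[Gal(b1-4)GlcNAc(b1-6)]Gal(b1-4)Glc",
    "Gal(b1-3)GalNAc",
    "Gal(b1-3)[GlcNAc(b1-6)]GalNAc",
    "GlcNAc(b1-3)GalNAc",
    "Gal(b1-4)GlcNAc(b1-6)[Gal(b1-3)]GalNAc",
    "Neu5Ac(a2-3)Gal(b1-3)GalNAc",
    "Neu5Ac(a2-3)Gal(b1-3)[Neu5Ac(a2-6)]GalNAc",
    "Neu5Ac(a2-6)GalNAc",
    "Neu5Ac(a2-3)[GalNAc(b1-4)]Gal(b1-4)Glc",
    "Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc",
    "Neu5Ac(a2-8)Neu5Ac(a2-3)Gal(b1-4)Glc",
    "Neu5Ac(a2-3)Gal(b1-3)GalNAc(b1-4)[Neu5Ac(a2-3)]Gal(b1-4)Glc",
    "Gal(b1-3)GalNAc(b1-4)Gal(b1-4)Glc",
    "Gal(a1-4)Gal(b1-4)Glc",
    "GalNAc(b1-3)Gal(a1-4)Gal(b1-4)Glc",
    "Gal(a1-3)Gal(b1-4)Glc",
    "Fuc(a1-2)[Gal(a1-3)]Gal(b1-4)GlcNAc",
    "Fuc(a1-2)[GalNAc(a1-3)]Gal(b1-4)GlcNAc",
    "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]"
    "Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)"
    "[Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)"
    "[Fuc(a1-6)]GlcNAc",
    "GlcNAc(b1-2)Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)][GlcNAc(b1-4)]Man(b1-4)"
    "GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc",
    "GlcA(b1-3)Gal(b1-4)GlcNAc",
    "Rha(a1-2)Rha(a1-3)Rha",
    "Glc(a1-4)Glc(a1-4)Glc",
    "Glc(a1-6)Glc(a1-4)Glc",
    "Xyl(b1-4)Xyl(b1-4)Xyl",
    "GlcA(b1-4)Xyl(b1-4)Xyl",
    "Man(a1-2)Man(a1-2)Man(a1-3)Man",
    "Fuc(a1-2)Gal(b1-3)GalNAc",
)

#: Oxford codes paired with hand-derived canonical expansions
OXFORD_CASES: tuple[tuple[str, str], ...] = (
    ("M3", "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("M5", "Man(a1-3)[Man(a1-6)]Man(a1-6)[Man(a1-3)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("M6", "Man(a1-2)Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("M9", "Man(a1-2)Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A1", "GlcNAc(b1-2)Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A2", "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("FA1", "GlcNAc(b1-2)Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("FA2", "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("A2B", "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)][GlcNAc(b1-4)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("FA2B", "GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)][GlcNAc(b1-4)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("A2G1", "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A2G2", "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("FA2G1", "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("FA2G2", "Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("FA2G2S1", "Neu5Ac(a2-?)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("FA2G2S2", "Neu5Ac(a2-?)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Neu5Ac(a2-?)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
    ("A2G2S2", "Neu5Ac(a2-?)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Neu5Ac(a2-?)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A2G2S(6)2", "Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)[Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A2G(3)2S(3)2", "Neu5Ac(a2-3)Gal(b1-3)GlcNAc(b1-2)Man(a1-3)[Neu5Ac(a2-3)Gal(b1-3)GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A3", "GlcNAc(b1-2)[GlcNAc(b1-4)]Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("A4", "GlcNAc(b1-2)[GlcNAc(b1-4)]Man(a1-3)[GlcNAc(b1-2)[GlcNAc(b1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"),
    ("FA3", "GlcNAc(b1-2)[GlcNAc(b1-4)]Man(a1-3)[GlcNAc(b1-2)Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc"),
)


# ---------------------------------------------------------------------------
# encoders: canonical IUPAC tree -> foreign nomenclature
# ---------------------------------------------------------------------------

_GWS_NAMES = {
    "Glc": "Glc", "Gal": "Gal", "Man": "Man", "GlcNAc": "GlcNAc",
    "GalNAc": "GalNAc", "Fuc": "Fuc", "Neu5Ac": "NeuAc", "Neu5Gc": "NeuGc",
    "Xyl": "Xyl", "GlcA": "GlcA", "Rha": "Rha", "Kdn": "KDN",
}

_WURCS_DESCRIPTORS = {
    "Glc": ("a2122h", "1", "1-5", ()),
    "Gal": ("a2112h", "1", "1-5", ()),
    "Man": ("a1122h", "1", "1-5", ()),
    "GlcNAc": ("a2122h", "1", "1-5", (("2", "NCC/3=O"),)),
    "GalNAc": ("a2112h", "1", "1-5", (("2", "NCC/3=O"),)),
    "Fuc": ("a1221m", "1", "1-5", ()),
    "Rha": ("a2211m", "1", "1-5", ()),
    "Xyl": ("a212h", "1", "1-5", ()),
    "GlcA": ("a2122A", "1", "1-5", ()),
    "Neu5Ac": ("Aad21122h", "2", "2-6", (("5", "NCC/3=O"),)),
    "Neu5Gc": ("Aad21122h", "2", "2-6", (("5", "NCCO/3=O"),)),
    "Kdn": ("Aad21122h", "2", "2-6", ()),
}

_GLYCOCT_BASES = {
    "Glc": ("dglc", "HEX", "1:5", "", None),
    "Gal": ("dgal", "HEX", "1:5", "", None),
    "Man": ("dman", "HEX", "1:5", "", None),
    "GlcNAc": ("dglc", "HEX", "1:5", "", ("2", "n-acetyl")),
    "GalNAc": ("dgal", "HEX", "1:5", "", ("2", "n-acetyl")),
    "Fuc": ("lgal", "HEX", "1:5", "|6:d", None),
    "Rha": ("lman", "HEX", "1:5", "|6:d", None),
    "Xyl": ("dxyl", "PEN", "1:5", "", None),
    "GlcA": ("dglc", "HEX", "1:5", "|6:a", None),
    "Neu5Ac": ("dgro-dgal", "NON", "2:6", "|1:a|2:keto|3:d", ("5", "n-acetyl")),
    "Neu5Gc": ("dgro-dgal", "NON", "2:6", "|1:a|2:keto|3:d", ("5", "n-glycolyl")),
    "Kdn": ("dgro-dgal", "NON", "2:6", "|1:a|2:keto|3:d", None),
}

_LINEARCODE_LETTERS = {
    "Gal": "A", "Glc": "G", "GlcNAc": "GN", "GalNAc": "AN", "Man": "M",
    "Fuc": "F", "Neu5Ac": "NN", "Neu5Gc": "NJ", "Xyl": "X", "GlcA": "U",
    "Rha": "H", "Kdn": "K",
}

_EXTENDED_PARTS = {
    # token -> (enantiomer, stem+ring+suffix spelling)
    "Glc": ("D", "Glcp"), "Gal": ("D", "Galp"), "Man": ("D", "Manp"),
    "GlcNAc": ("D", "GlcpNAc"), "GalNAc": ("D", "GalpNAc"),
    "Fuc": ("L", "Fucp"), "Rha": ("L", "Rhap"), "Xyl": ("D", "Xylp"),
    "GlcA": ("D", "GlcpA"), "Neu5Ac": (None, "Neup5Ac"),
    "Neu5Gc": (None, "Neup5Gc"), "Kdn": (None, "Kdnp"),
}

_GLYCAM_PARTS = {
    "Glc": ("D", "Glcp"), "Gal": ("D", "Galp"), "Man": ("D", "Manp"),
    "GlcNAc": ("D", "GlcpNAc"), "GalNAc": ("D", "GalpNAc"),
    "Fuc": ("L", "Fucp"), "Rha": ("L", "Rhap"), "Xyl": ("D", "Xylp"),
    "GlcA": ("D", "GlcpA"), "Neu5Ac": ("D", "Neup5Ac"),
    "Neu5Gc": ("D", "Neup5Gc"), "Kdn": ("D", "Kdnp"),
}


class EncodingUnsupported(GlycanError):
    """This glycan cannot be written in the requested nomenclature."""


def _tree(canonical: str) -> GlycanTree:
    t = parse_iupac_to_tree(canonical)
    if t.floating:
        raise EncodingUnsupported("floating parts are not encoded")
    return t


def _require(table: dict, token: str):
    if token not in table:
        raise EncodingUnsupported(f"no encoding for residue {token}")
    return table[token]


def _int_link(link: Linkage) -> tuple[str, str, str]:
    if link.anomer == "?" or link.donor == "?" or link.acceptors == ("?",):
        raise EncodingUnsupported("wildcard linkage not encodable")
    if len(link.acceptors) != 1:
        raise EncodingUnsupported("narrow-ambiguity linkage not encodable")
    return link.anomer, link.donor, str(link.acceptors[0])


def encode_glycam(canonical: str) -> str:
    t = _tree(canonical)

    def emit(node: Node, link_text: str) -> str:
        en, name = _require(_GLYCAM_PARTS, node.residue.to_token())
        parts = []
        if node.children:
            first, flink = node.children[0]
            parts.append(emit(first, _glycam_link(flink)))
            for child, clink in node.children[1:]:
                parts.append(f"[{emit(child, _glycam_link(clink))}]")
        parts.append(f"{en}{name}{link_text}")
        return "".join(parts)

    def _glycam_link(link: Linkage) -> str:
        a, d, acc = _int_link(link)
        return f"{a}{d}-{acc}"

    root_anomer = "b"
    en, name = _require(_GLYCAM_PARTS, t.root.residue.to_token())
    parts = []
    if t.root.children:
        first, flink = t.root.children[0]
        parts.append(emit(first, _glycam_link(flink)))
        for child, clink in t.root.children[1:]:
            parts.append(f"[{emit(child, _glycam_link(clink))}]")
    donor = "2" if name.startswith(("Neup", "Kdn")) else "1"
    parts.append(f"{en}{name}{'a' if donor == '2' else root_anomer}{donor}-OH")
    return "".join(parts)


def encode_iupac_extended(canonical: str) -> str:
    t = _tree(canonical)
    greek = {"a": "α", "b": "β"}

    def emit(node: Node, link: Linkage | None) -> str:
        en, name = _require(_EXTENDED_PARTS, node.residue.to_token())
        parts = []
        if node.children:
            first, flink = node.children[0]
            parts.append(emit(first, flink))
            for child, clink in node.children[1:]:
                parts.append(f"[{emit(child, clink)}]")
        text = (f"{en}-" if en else "") + name
        if link is not None:
            a, d, acc = _int_link(link)
            text = f"{greek[a]}-{text}-({d}→{acc})-"
        parts.append(text)
        return "".join(parts)

    return emit(t.root, None)


def encode_linearcode(canonical: str) -> str:
    t = _tree(canonical)

    def emit(node: Node, link: Linkage | None) -> str:
        letter = _require(_LINEARCODE_LETTERS, node.residue.to_token())
        parts = []
        if node.children:
            first, flink = node.children[0]
            parts.append(emit(first, flink))
            for child, clink in node.children[1:]:
                parts.append(f"({emit(child, clink)})")
        text = letter
        if link is not None:
            a, _d, acc = _int_link(link)
            text += f"{a}{acc}"
        parts.append(text)
        return "".join(parts)

    return emit(t.root, None) + ";"


def encode_gws(canonical: str) -> str:
    t = _tree(canonical)

    def seg(node: Node, acc: str, anomer: str, donor: str) -> str:
        name = _require(_GWS_NAMES, node.residue.to_token())
        en = "L" if node.residue.base_name in ("Fuc", "Rha") else "D"
        return f"--{acc}{anomer}{donor}{en}-{name},p"

    def walk(node: Node) -> str:
        if not node.children:
            return ""
        out = []
        kids = node.children
        if len(kids) > 1:
            inner = []
            for child, link in kids[:-1]:
                a, d, acc = _int_link(link)
                inner.append(f"({seg(child, acc, a, d)}{walk(child)})")
            child, link = kids[-1]
            a, d, acc = _int_link(link)
            out.append("(" + "".join(inner) + seg(child, acc, a, d) + walk(child) + ")")
        else:
            child, link = kids[0]
            a, d, acc = _int_link(link)
            out.append(seg(child, acc, a, d) + walk(child))
        return "".join(out)

    root = t.root
    name = _require(_GWS_NAMES, root.residue.to_token())
    en = "L" if root.residue.base_name in ("Fuc", "Rha") else "D"
    donor = "2" if root.residue.base_name in ("Neu5Ac", "Neu5Gc", "Kdn") else "1"
    head = f"freeEnd--?b{donor}{en}-{name},p" if donor == "1" else f"freeEnd--?a{donor}{en}-{name},p"
    return head + walk(root) + "$MONO,Und,-H,0,redEnd"


def encode_kcf(canonical: str, entry: str = "G99999") -> str:
    t = _tree(canonical)
    nodes: list[tuple[str, int, int]] = []
    edges: list[tuple[int, str, int, str]] = []

    def assign(node: Node, depth: int, ylevel: list[int]) -> int:
        idx = len(nodes) + 1
        nodes.append((node.residue.to_token(), -10 * depth, -5 * ylevel[0]))
        for child, link in node.children:
            ylevel[0] += 1
            cidx = assign(child, depth + 1, ylevel)
            a, d, acc = _int_link(link)
            edges.append((cidx, f"{a}{d}", idx, acc))
        return idx

    assign(t.root, 0, [0])
    lines = [f"ENTRY     {entry}          Glycan", f"NODE      {len(nodes)}"]
    for i, (name, x, y) in enumerate(nodes, 1):
        lines.append(f"            {i}   {name}   {x}   {y}")
    lines.append(f"EDGE      {len(edges)}")
    for i, (child, ad, parent, acc) in enumerate(edges, 1):
        lines.append(f"            {i}   {child}:{ad}   {parent}:{acc}")
    lines.append("///")
    return "\n".join(lines)


def encode_glycoct(canonical: str) -> str:
    t = _tree(canonical)
    res_lines: list[str] = []
    lin_lines: list[str] = []
    counter = [0]

    def new_idx() -> int:
        counter[0] += 1
        return counter[0]

    def add_residue(node: Node, anomer: str) -> int:
        token = node.residue.to_token()
        stem, superclass, ring, modifiers, subst = _require(_GLYCOCT_BASES, token)
        idx = new_idx()
        res_lines.append(f"{idx}b:{anomer}-{stem}-{superclass}-{ring}{modifiers}")
        if subst is not None:
            pos, name = subst
            sidx = new_idx()
            res_lines.append(f"{sidx}s:{name}")
            lin_lines.append(f"{{n}}:{idx}d({pos}+1){sidx}n")
        return idx

    def walk(node: Node, idx: int):
        for child, link in node.children:
            a, d, acc = _int_link(link)
            cidx = add_residue(child, a)
            lin_lines.append(f"{{n}}:{idx}o({acc}+{d}){cidx}d")
            walk(child, cidx)

    root_idx = add_residue(t.root, "x")
    walk(t.root, root_idx)
    out = ["RES"] + res_lines
    if lin_lines:
        out.append("LIN")
        out += [ln.format(n=i) for i, ln in enumerate(lin_lines, 1)]
    return "\n".join(out)


def encode_wurcs(canonical: str) -> str:
    t = _tree(canonical)
    instances: list[str] = []  # descriptor per residue instance
    links: list[str] = []

    def letters(i: int) -> str:
        out = ""
        i += 1
        while i > 0:
            i, r = divmod(i - 1, 26)
            out = chr(ord("a") + r) + out
        return out

    def descriptor(node: Node, anomer: str) -> str:
        token = node.residue.to_token()
        skeleton, apos, ring, substs = _require(_WURCS_DESCRIPTORS, token)
        a = {"a": "a", "b": "b", "?": "x"}[anomer]
        desc = f"{skeleton}-{apos}{a}_{ring}"
        for pos, code in substs:
            desc += f"_{pos}*{code}"
        return desc

    def walk(node: Node, idx: int):
        for child, link in node.children:
            a, d, acc = _int_link(link)
            cidx = len(instances)
            instances.append(descriptor(child, a))
            links.append(f"{letters(idx)}{acc}-{letters(cidx)}{d}")
            walk(child, cidx)

    instances.append(descriptor(t.root, "?"))
    walk(t.root, 0)
    unique: list[str] = []
    seq: list[int] = []
    for desc in instances:
        if desc not in unique:
            unique.append(desc)
        seq.append(unique.index(desc) + 1)
    body = (
        f"{len(unique)},{len(instances)},{len(links)}/"
        + "".join(f"[{d}]" for d in unique)
        + "/" + "-".join(map(str, seq)) + "/" + "_".join(links)
    )
    return "WURCS=2.0/" + body


ENCODERS = {
    NomenclatureKind.WURCS: encode_wurcs,
    NomenclatureKind.GLYCOCT: encode_glycoct,
    NomenclatureKind.LINEARCODE: encode_linearcode,
    NomenclatureKind.GLYCAM: encode_glycam,
    NomenclatureKind.KCF: encode_kcf,
    NomenclatureKind.IUPAC_EXTENDED: encode_iupac_extended,
    NomenclatureKind.GWS: encode_gws,
}


# ---------------------------------------------------------------------------
# fixture corpus
# ---------------------------------------------------------------------------


@dataclass
class FixtureCase:
    """One canonical glycan with variant encodings across nomenclatures."""

    canonical: str
    variants: list[tuple[str, NomenclatureKind]] = field(default_factory=list)
    provenance: str = "hand_built"


def build_corpus(seed: int = 7, dialect_variants: int = 2) -> list[FixtureCase]:
    """Programmatically build the full fixture corpus.

    Each curated canonical glycan is encoded into every applicable
    nomenclature; seeded IUPAC dialect variants are added on top, and the
    hand-derived Oxford cases are appended.
    """
    from .pipeline import generate_dialect_variants  # late import (cycle)

    corpus: list[FixtureCase] = []
    for i, canonical in enumerate(CANONICAL_GLYCANS):
        case = FixtureCase(canonical)
        for kind, encoder in ENCODERS.items():
            try:
                case.variants.append((encoder(canonical), kind))
            except EncodingUnsupported:
                continue
        for v in generate_dialect_variants(canonical, seed + i, dialect_variants):
            case.variants.append((v, NomenclatureKind.IUPAC_OR_CSDB))
        case.provenance = f"generated(seed={seed})"
        corpus.append(case)
    for code, canonical in OXFORD_CASES:
        corpus.append(
            FixtureCase(canonical, [(code, NomenclatureKind.OXFORD)], "hand_built")
        )
    return corpus


# ---------------------------------------------------------------------------
# random glycan trees (synthetic data for property tests)
# ---------------------------------------------------------------------------

_RANDOM_TOKENS = (
    "Glc", "Gal", "Man", "GlcNAc", "GalNAc", "Fuc", "Xyl", "Neu5Ac",
    "Neu5Gc", "Kdn", "GlcA", "IdoA", "Rha", "Hex", "HexNAc", "L-Gal",
    "Galf", "Gal6S", "GlcNAc6S", "Man6P", "GalOS", "Gal3Me",
)


def random_linkage(rng: random.Random) -> Linkage:
    anomer = rng.choice("ab?")
    donor = rng.choice(("1", "1", "1", "2", "?"))
    roll = rng.random()
    if roll < 0.15:
        acceptors: tuple = ("?",)
    elif roll < 0.25:
        lo = rng.randint(2, 5)
        acceptors = (lo, lo + rng.randint(1, 3))
    else:
        acceptors = (rng.randint(2, 9),)
    return Linkage(anomer, donor, acceptors)


def random_tree(rng: random.Random, max_nodes: int = 15) -> GlycanTree:
    """A random labeled glycan tree with at most ``max_nodes`` residues."""
    n = rng.randint(1, max_nodes)

    def make_node() -> Node:
        return Node(Monosaccharide.from_token(rng.choice(_RANDOM_TOKENS)))

    root = make_node()
    nodes = [root]
    for _ in range(n - 1):
        parent = rng.choice(nodes)
        child = make_node()
        parent.children.append((child, random_linkage(rng)))
        nodes.append(child)
    floating = []
    if rng.random() < 0.2:
        part = make_node()
        floating.append((part, Linkage(rng.choice("ab?"), rng.choice("12?"), ("?",))))
    return GlycanTree(root, floating)
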