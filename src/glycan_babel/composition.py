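"""Monosaccharide composition parsing and canonicalization.

Supports the three shorthand families used across glycomics:

* single-letter: ``H5N4F1A2``
* named: ``Hex5HexNAc4Fuc1Neu5Ac2``
* parenthesized, with an optional ``+`` core appendix:
  ``(Hex)3 (HexNAc)1 (NeuAc)1 + (Man)3(GlcNAc)2``

All styles of the same multiset parse to an identical :class:`Composition`;
serialization uses one fixed class order, so the canonical string is unique.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import GlycanParseError

#: canonical class order for serialization
CLASS_ORDER = (
    "Hex", "HexNAc", "dHex", "Neu5Ac", "Neu5Gc", "Pen", "HexA",
    "Kdn", "S", "P", "Me", "Ac",
)

#: named tokens (and concrete residues) folded into composition classes
FOLD = {
    "Hex": "Hex", "Glc": "Hex", "Gal": "Hex", "Man": "Hex",
    "HexNAc": "HexNAc", "GlcNAc": "HexNAc", "GalNAc": "HexNAc",
    "ManNAc": "HexNAc",
    "dHex": "dHex", "Fuc": "dHex", "Rha": "dHex", "DeoxyHex": "dHex",
    "Neu5Ac": "Neu5Ac", "NeuAc": "Neu5Ac", "NeuNAc": "Neu5Ac",
    "NANA": "Neu5Ac", "Sia": "Neu5Ac",
    "Neu5Gc": "Neu5Gc", "NeuGc": "Neu5Gc",
    "Pen": "Pen", "Pent": "Pen", "Xyl": "Pen", "Ara": "Pen",
    "HexA": "HexA", "GlcA": "HexA", "GalA": "HexA", "IdoA": "HexA",
    "Kdn": "Kdn", "KDN": "Kdn",
    "S": "S", "Su": "S", "Sulf": "S", "Sulfate": "S", "Sulfo": "S",
    "P": "P", "Phos": "P", "Phosphate": "P",
    "Me": "Me", "Methyl": "Me",
    "Ac": "Ac", "Acetyl": "Ac",
}

_NAMED_ALT = "|".join(sorted(FOLD, key=len, reverse=True))
_NAMED_ITEM = re.compile(rf"({_NAMED_ALT})(\d+)")
_NAMED_FULL = re.compile(rf"^(?:(?:{_NAMED_ALT})\d+)+$")
_LETTER_FULL = re.compile(r"^(?:[HNFAGSP]\d+)+$")
_LETTER_ITEM = re.compile(r"([HNFAGSP])(\d+)")
_PAREN_ITEM = re.compile(rf"\(\s*({_NAMED_ALT})\s*\)\s*(\d+)")
_PAREN_FULL = re.compile(
    rf"^\s*(?:\(\s*(?:{_NAMED_ALT})\s*\)\s*\d+\s*)+"
    rf"(?:\+\s*(?:\(\s*(?:{_NAMED_ALT})\s*\)\s*\d*\s*)+)?$"
)

#: single-letter map; 'S' is context-dependent (see parse_composition)
LETTERS = {"H": "Hex", "N": "HexNAc", "F": "dHex", "A": "Neu5Ac",
           "G": "Neu5Gc", "P": "P"}


@dataclass(frozen=True)
class Composition:
    """Multiset of monosaccharide classes; zero counts are never stored."""

    counts: tuple[tuple[str, int], ...] = field(default=())

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Composition":
        bad = set(d) - set(CLASS_ORDER)
        if bad:
            raise GlycanParseError(f"unknown composition class(es): {sorted(bad)}")
        items = tuple(
            (c, d[c]) for c in CLASS_ORDER if d.get(c, 0) > 0
        )
        if not items:
            raise GlycanParseError("empty composition")
        if any(v < 0 for v in d.values()):
            raise GlycanParseError("negative count in composition")
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


def parse_composition(s: str) -> Composition:
    """Parse any supported composition style into a canonical Composition."""
    raw = s
    s = s.strip()
    if not s:
        raise GlycanParseError("empty composition string")
    counts: dict[str, int] = {}

    def add(cls_name: str, n: int):
        counts[cls_name] = counts.get(cls_name, 0) + n

    if "(" in s:
        if not _PAREN_FULL.match(s):
            rest = re.sub(_PAREN_ITEM, "", s).replace("+", "").strip()
            raise GlycanParseError(f"cannot parse composition {raw!r}: {rest!r}")
        for name, n in _PAREN_ITEM.findall(s):
            add(FOLD[name], int(n))
        return Composition.from_dict(counts)

    s = re.sub(r"\s+", "", s)
    if _NAMED_FULL.match(s):
        for name, n in _NAMED_ITEM.findall(s):
            add(FOLD[name], int(n))
        return Composition.from_dict(counts)

    if _LETTER_FULL.match(s):
        letters = {m[0] for m in _LETTER_ITEM.findall(s)}
        # 'S' reads as sialic acid in plain H/N/F context, sulfate when a
        # dedicated sialic-acid letter is already present
        smap = dict(LETTERS)
        smap["S"] = "S" if "A" in letters else "Neu5Ac"
        for letter, n in _LETTER_ITEM.findall(s):
            add(smap[letter], int(n))
        return Composition.from_dict(counts)

    raise GlycanParseError(f"cannot parse composition {raw!r}")


def composition_to_string(c: Composition) -> str:
    """Unique serialization in the fixed class order."""
    if not c.counts:
        raise GlycanParseError("empty composition")
    return "".join(f"{name}{n}" for name, n in c.counts)


def detect_composition(s: str) -> bool:
    """True iff ``s`` is a composition shorthand (and not a structure)."""
    s = s.strip()
    if not s or re.search(r"\([ab?][12?]-", s):
        return False
    if "(" in s:
        return bool(_PAREN_FULL.match(s))
    t = re.sub(r"\s+", "", s)
    return bool(_NAMED_FULL.match(t) or _LETTER_FULL.match(t))


def canonicalize_composition(s: str) -> str:
    """Parse + re-serialize: one canonical string per composition."""
    return composition_to_string(parse_composition(s))
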