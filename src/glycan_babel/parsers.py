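"""Rudimentary parsers from foreign nomenclatures into raw IUPAC-like strings.

Each parser converts its source language into a flat string *resembling*
IUPAC-condensed and nothing more; shared clean-up (namespace, linkage
spelling, bracket convention, feasibility) is deliberately left to the
common stem, which every parser output is piped through downstream.

Graph-shaped formats (WURCS, GlycoCT, KCF) are first read into a
:class:`ResidueLinkTable` and then serialized.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GlycanParseError, StructureError, UnsupportedTokenError

_DATA = Path(__file__).parent / "data"
_WURCS = json.loads((_DATA / "wurcs_tokens.json").read_text(encoding="utf-8"))
_LINEARCODE = json.loads(
    (_DATA / "linearcode_tokens.json").read_text(encoding="utf-8")
)["residues"]
_LINEARCODE_BY_LENGTH = sorted(_LINEARCODE, key=len, reverse=True)


# ---------------------------------------------------------------------------
# residue/link table
# ---------------------------------------------------------------------------


@dataclass
class ResidueLinkTable:
    """Intermediate representation for graph-shaped formats.

    ``residues`` maps an index to a residue descriptor string (raw IUPAC
    token); ``links`` holds (child, anomer, donor, parent, acceptor) with
    positions as strings ('?' allowed).
    """

    residues: dict[int, str] = field(default_factory=dict)
    links: list[tuple[int, str, str, int, str]] = field(default_factory=list)

    def serialize(self) -> str:
        for child, _, _, parent, _ in self.links:
            if child not in self.residues or parent not in self.residues:
                raise StructureError(
                    f"link references undefined residue ({child}->{parent})"
                )
        parents: dict[int, int] = {}
        children: dict[int, list[tuple[int, str, str, str]]] = {}
        for child, anomer, donor, parent, acc in self.links:
            if child in parents:
                raise StructureError(f"residue {child} has multiple parents")
            parents[child] = parent
            children.setdefault(parent, []).append((child, anomer, donor, acc))
        roots = [i for i in self.residues if i not in parents]
        if len(roots) != 1:
            raise StructureError(
                f"expected exactly one root residue, found {len(roots)}"
            )
        visited: set[int] = set()

        def emit(idx: int) -> str:
            if idx in visited:
                raise StructureError("cycle in residue links")
            visited.add(idx)
            parts = []
            kids = children.get(idx, [])
            for n, (child, anomer, donor, acc) in enumerate(kids):
                text = f"{emit(child)}({anomer}{donor}-{acc})"
                parts.append(text if n == 0 else f"[{text}]")
            parts.append(self.residues[idx])
            return "".join(parts)

        out = emit(roots[0])
        if len(visited) != len(self.residues):
            raise StructureError("disconnected residues in graph")
        return out


# ---------------------------------------------------------------------------
# WURCS 2.0
# ---------------------------------------------------------------------------

_WURCS_DESC_RE = re.compile(r"^([A-Za-z0-9<>]+)-([1-9])([abxu])$")
_WURCS_SUBST_RE = re.compile(r"^([0-9?]+)\*(.+)$")
_WURCS_LINK_RE = re.compile(r"^([a-zA-Z]+)([0-9?]+)-([a-zA-Z]+)([0-9?]+)$")

_HEXOSE_FUSIBLE = {"Glc", "Gal", "Man", "All", "Alt", "Gul", "Ido", "Tal", "Hex"}


def _wurcs_token(descriptor: str) -> tuple[str, str, str]:
    """Map one unique-residue descriptor to (token, anomer, anomeric_pos)."""
    parts = descriptor.split("_")
    m = _WURCS_DESC_RE.match(parts[0])
    ring_part_start = 1
    if not m:
        raise UnsupportedTokenError(descriptor, "WURCS residue descriptor")
    skeleton, apos, anomer = m.groups()
    base = _WURCS["skeletons"].get(skeleton)
    if base is None:
        raise UnsupportedTokenError(descriptor, "WURCS skeleton")
    # parts[1] is the ring closure ("1-5"); substituents follow
    mods: list[tuple[str, str]] = []
    for part in parts[ring_part_start + 1 :] if len(parts) > 1 else []:
        sm = _WURCS_SUBST_RE.match(part)
        if not sm:
            raise UnsupportedTokenError(descriptor, "WURCS substituent")
        tag = _WURCS["substituents"].get(sm.group(2))
        if tag is None:
            raise UnsupportedTokenError(descriptor, "WURCS substituent code")
        mods.append((sm.group(1), tag))
    token = base
    if base == "Neu":  # sialic skeleton: the C5 N-acyl selects the name
        named = {t for p, t in mods if p == "5"}
        if "NAc" in named:
            token, mods = "Neu5Ac", [(p, t) for p, t in mods if (p, t) != ("5", "NAc")]
        elif "NGc" in named:
            token, mods = "Neu5Gc", [(p, t) for p, t in mods if (p, t) != ("5", "NGc")]
        else:
            token = "Kdn"
    rest = []
    for pos, tag in mods:
        if tag in ("NAc", "N") and pos == "2" and token in _HEXOSE_FUSIBLE:
            token += tag
        elif tag in ("NAc", "NGc", "N"):
            raise UnsupportedTokenError(descriptor, "WURCS N-substituent placement")
        else:
            rest.append(f"{pos}{tag}")
    token += "".join(rest)
    anomer = {"a": "a", "b": "b", "x": "?", "u": "?"}[anomer]
    return token, anomer, apos


def _wurcs_letters_to_index(letters: str) -> int:
    idx = 0
    for ch in letters.lower():
        idx = idx * 26 + (ord(ch) - ord("a") + 1)
    return idx - 1


def parse_wurcs(s: str) -> str:
    """WURCS=2.0/<u>,<r>,<l>/[desc].../seq/link-list -> raw IUPAC string."""
    s = s.strip()
    if not s.startswith("WURCS"):
        raise GlycanParseError("not a WURCS string")
    body = s.split("/", 1)
    if len(body) != 2:
        raise GlycanParseError("malformed WURCS string")
    # section split: counts / [descriptors...] / sequence / links
    mdesc = re.match(r"^([^\[]*)((?:\[[^\]]*\])+)/([0-9\-]+)/?(.*)$", body[1])
    if not mdesc:
        raise GlycanParseError("malformed WURCS sections")
    descriptors = re.findall(r"\[([^\]]*)\]", mdesc.group(2))
    seq = mdesc.group(3)
    linkpart = mdesc.group(4)

    unique = [_wurcs_token(d) for d in descriptors]
    instances = []
    for num in seq.split("-"):
        i = int(num) - 1
        if i < 0 or i >= len(unique):
            raise GlycanParseError(f"WURCS sequence index {num} out of range")
        instances.append(unique[i])

    table = ResidueLinkTable()
    for idx, (token, _anomer, _apos) in enumerate(instances):
        table.residues[idx] = token
    for entry in [e for e in linkpart.split("_") if e]:
        lm = _WURCS_LINK_RE.match(entry)
        if not lm:
            raise UnsupportedTokenError(entry, "WURCS link")
        i1 = _wurcs_letters_to_index(lm.group(1))
        p1 = lm.group(2)
        i2 = _wurcs_letters_to_index(lm.group(3))
        p2 = lm.group(4)
        for i in (i1, i2):
            if i not in table.residues:
                raise GlycanParseError(f"WURCS link references residue {i + 1}")
        # the donor side connects through its own anomeric carbon
        if p2 == instances[i2][2]:
            parent, acc, child, donor = i1, p1, i2, p2
        elif p1 == instances[i1][2]:
            parent, acc, child, donor = i2, p2, i1, p1
        else:
            parent, acc, child, donor = i1, p1, i2, p2
        anomer = instances[child][1]
        table.links.append((child, anomer, donor, parent, acc))
    return table.serialize()


# ---------------------------------------------------------------------------
# GlycoCT (condensed)
# ---------------------------------------------------------------------------

_GCT_BASE_RE = re.compile(
    r"^(\d+)b:([abxo?u])-(?:[dl]gro-)?([dl]?)([a-z]{3})-([A-Z]{3})-(\d+:\d+)((?:\|[\d,]+:[a-z]+)*)$"
)
_GCT_SUBST_RE = re.compile(r"^(\d+)s:([a-z\-()]+)$")
_GCT_LIN_RE = re.compile(
    r"^(\d+):(\d+)([odn])\((-?[\d?]+)\+(-?[\d?]+)\)(\d+)([odn])$"
)

_GCT_STEMS = {
    "glc": "Glc", "gal": "Gal", "man": "Man", "all": "All", "alt": "Alt",
    "gul": "Gul", "ido": "Ido", "tal": "Tal", "xyl": "Xyl", "rib": "Rib",
    "lyx": "Lyx", "ara": "Ara", "fru": "Fru",
}
_GCT_SUBSTITUENTS = {
    "n-acetyl": "NAc", "n-glycolyl": "NGc", "amino": "N",
    "sulfate": "S", "phosphate": "P", "methyl": "Me", "acetyl": "Ac",
}


def _gct_pos(p: str) -> str:
    return "?" if p in ("-1", "?") else p


def parse_glycoct(s: str) -> str:
    """GlycoCT condensed (RES/LIN sections) -> raw IUPAC string."""
    lines = [ln.strip() for ln in s.strip().splitlines() if ln.strip()]
    section = None
    bases: dict[int, dict] = {}
    substs: dict[int, str] = {}
    lin_entries = []
    for ln in lines:
        if ln in ("RES", "LIN", "UND"):
            section = ln
            continue
        if section == "RES":
            mb = _GCT_BASE_RE.match(ln)
            if mb:
                idx = int(mb.group(1))
                anomer = {"a": "a", "b": "b"}.get(mb.group(2), "?")
                stem = _GCT_STEMS.get(mb.group(4))
                if stem is None:
                    raise UnsupportedTokenError(ln, "GlycoCT stem")
                ring = mb.group(6)
                modifiers = re.findall(r"\|([\d,]+):([a-z]+)", mb.group(7))
                superclass = mb.group(5)
                bases[idx] = {
                    "anomer": anomer,
                    "en": mb.group(3) or "d",
                    "stem": stem,
                    "superclass": superclass,
                    "ring": ring,
                    "modifiers": modifiers,
                    "mods": [],
                }
                continue
            ms = _GCT_SUBST_RE.match(ln)
            if ms:
                substs[int(ms.group(1))] = ms.group(2)
                continue
            raise GlycanParseError(f"cannot parse GlycoCT RES line: {ln!r}")
        if section == "LIN":
            ml = _GCT_LIN_RE.match(ln)
            if not ml:
                raise GlycanParseError(f"cannot parse GlycoCT LIN line: {ln!r}")
            lin_entries.append(ml.groups())
    if not bases:
        raise GlycanParseError("GlycoCT input has no base residues")

    table = ResidueLinkTable()
    glyco_links = []
    for _lid, parent, _pk, ppos, cpos, child, _ck in lin_entries:
        parent_i, child_i = int(parent), int(child)
        if child_i in substs:
            if parent_i not in bases:
                raise StructureError(f"substituent {child_i} on unknown residue")
            tag = _GCT_SUBSTITUENTS.get(substs[child_i])
            if tag is None:
                raise UnsupportedTokenError(substs[child_i], "GlycoCT substituent")
            bases[parent_i]["mods"].append((_gct_pos(ppos), tag))
        elif child_i in bases and parent_i in bases:
            glyco_links.append((child_i, parent_i, _gct_pos(ppos), _gct_pos(cpos)))
        else:
            raise StructureError(f"GlycoCT LIN references undefined residue: {_lid}")

    for idx, info in bases.items():
        table.residues[idx] = _gct_token(info)
    for child_i, parent_i, acc, donor in glyco_links:
        table.links.append((child_i, bases[child_i]["anomer"], donor, parent_i, acc))
    return table.serialize()


def _gct_token(info: dict) -> str:
    stem, superclass = info["stem"], info["superclass"]
    mods = list(info["mods"])
    deoxy6 = any(p == "6" and kind == "d" for p, kind in info["modifiers"])
    acid6 = any(p == "6" and kind == "a" for p, kind in info["modifiers"])
    token = stem
    if superclass == "NON" and stem == "Gal":
        # gro-gal nonulosonate skeleton = the sialic-acid core
        named = {t for _p, t in mods}
        if "NAc" in named:
            token = "Neu5Ac"
            mods = [m for m in mods if m[1] != "NAc"]
        elif "NGc" in named:
            token = "Neu5Gc"
            mods = [m for m in mods if m[1] != "NGc"]
        else:
            token = "Kdn"
        return token + "".join(f"{p}{t}" for p, t in mods)
    if deoxy6:
        if stem == "Gal" and info["en"] == "l":
            token = "Fuc"
        elif stem == "Man" and info["en"] == "l":
            token = "Rha"
        elif stem == "Glc":
            token = "Qui"
        else:
            token = stem
    elif acid6:
        token = stem + "A"
    if info["en"] == "l" and token not in ("Fuc", "Rha"):
        token = "L-" + token
    out_mods = []
    for pos, tag in mods:
        if tag in ("NAc", "N") and pos == "2":
            token += tag
        else:
            out_mods.append(f"{pos if pos != '?' else 'O'}{tag}")
    return token + "".join(out_mods)


# ---------------------------------------------------------------------------
# LinearCode
# ---------------------------------------------------------------------------


def parse_linearcode(s: str) -> str:
    """LinearCode (``Ab4GN;``) -> raw IUPAC; parens become branch brackets."""
    s = s.strip().rstrip(";")
    out = []
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch == "(":
            out.append("[")
            i += 1
            continue
        if ch == ")":
            out.append("]")
            i += 1
            continue
        token = None
        for code in _LINEARCODE_BY_LENGTH:
            if s.startswith(code, i):
                token = _LINEARCODE[code]
                i += len(code)
                break
        if token is None:
            raise UnsupportedTokenError(s[i], "LinearCode residue letter")
        out.append(token)
        if i < n and s[i] in "ab?":
            anomer = s[i]
            i += 1
            if i < n and s[i] in "123456789?":
                pos = s[i]
                i += 1
                donor = "2" if token.startswith(("Neu", "Kdn", "Kdo")) else "1"
                out.append(f"({anomer}{donor}-{pos})")
            # trailing anomer on the reducing end carries no linkage: drop
    return "".join(out)


# ---------------------------------------------------------------------------
# GLYCAM
# ---------------------------------------------------------------------------

_GLYCAM_RES_RE = re.compile(
    r"([DL])([A-Z][a-z]{2})([pf])([A-Za-z0-9]*?)([ab])([12])(?:-([1-9?]+)|-(OH|OME|OMe|OtBu|ol))"
)


def parse_glycam(s: str) -> str:
    """GLYCAM condensed (``DGalpb1-4DGlcpb1-OH``) -> raw IUPAC string."""
    s = s.strip()
    if not s.upper().endswith(("-OH", "-OME", "-OTBU", "-OL")):
        raise GlycanParseError("GLYCAM string lacks its aglycon terminus")
    out = []
    pos = 0
    terminus = None
    for m in _GLYCAM_RES_RE.finditer(s):
        out.append(s[pos : m.start()])  # brackets pass through
        en, stem, ring, suffix, anomer, donor, acc, term = m.groups()
        token = stem + (suffix or "")
        if ring == "f":
            token = stem + "f" + (suffix or "")
        token = f"{en}-{token}"  # stem decides whether the prefix is default
        if term:
            terminus = term.upper()
            out.append(token)
        else:
            out.append(f"{token}({anomer}{donor}-{acc})")
        pos = m.end()
    tail = s[pos:]
    if not out:
        raise GlycanParseError(f"cannot parse GLYCAM residues in {s!r}")
    out.append(tail)
    raw = "".join(out)
    if terminus == "OME":
        raw += "1Me"  # methyl aglycon retained as a reducing-end annotation
    return raw


# ---------------------------------------------------------------------------
# Oxford N-glycan shorthand
# ---------------------------------------------------------------------------

_OXFORD_TOKEN_RE = re.compile(
    r"F|A\d|B|G\d(?:\(\d\))?|G\(\d\)\d?|S\d(?:\(\d\))?|S\(\d\)\d?|M\d"
)

_OLIGOMANNOSE = {
    3: "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    5: "Man(a1-3)[Man(a1-6)]Man(a1-6)[Man(a1-3)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    6: "Man(a1-2)Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    7: "Man(a1-2)Man(a1-2)Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    8: "Man(a1-2)Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
    9: "Man(a1-2)Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-6)]Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
}


def parse_oxford(s: str) -> str:
    """Oxford shorthand (``FA2G2S2``) -> raw IUPAC built on the Man3 core."""
    s = s.strip()
    tokens = _OXFORD_TOKEN_RE.findall(s)
    if "".join(tokens) != s:
        leftover = _OXFORD_TOKEN_RE.sub("", s)
        raise UnsupportedTokenError(leftover, "Oxford token")
    fucose = False
    antennae = 0
    bisect = False
    gal: list[str] = []          # galactose linkage per decorated antenna
    sia: list[str] = []          # sialic linkage per decorated antenna
    mannose = None
    for tok in tokens:
        if tok == "F":
            fucose = True
        elif tok == "B":
            bisect = True
        elif tok[0] == "A":
            antennae = int(tok[1])
        elif tok[0] == "M":
            mannose = int(tok[1])
        elif tok[0] == "G":
            count, pos = _oxford_count_pos(tok)
            gal.extend([f"b1-{pos or '4'}"] * count)
        elif tok[0] == "S":
            count, pos = _oxford_count_pos(tok)
            sia.extend([f"a2-{pos or '?'}"] * count)

    if mannose is not None:
        if mannose not in _OLIGOMANNOSE:
            raise UnsupportedTokenError(f"M{mannose}", "Oxford oligomannose")
        core = _OLIGOMANNOSE[mannose]
        if fucose:
            core = core[: core.rfind("GlcNAc")] + "[Fuc(a1-6)]GlcNAc"
        return core

    if antennae > 4:
        raise UnsupportedTokenError(f"A{antennae}", "Oxford antenna count")
    # antenna positions filled left-to-right: the a1-3 arm first
    arm3_ant = ["b1-2"] if antennae >= 1 else []
    arm6_ant = ["b1-2"] if antennae >= 2 else []
    if antennae >= 3:
        arm3_ant.append("b1-4")
    if antennae >= 4:
        arm6_ant.append("b1-6")

    decorations = []
    total = len(arm3_ant) + len(arm6_ant)
    for i in range(total):
        g = gal[i] if i < len(gal) else None
        n = sia[i] if i < len(sia) else None
        decorations.append((g, n))

    def antenna(link: str, deco: tuple[str | None, str | None]) -> str:
        g, n = deco
        out = f"GlcNAc({link})"
        if g:
            out = f"Gal({g})" + out
            if n:
                out = f"Neu5Ac({n})" + out
        return out

    i = 0
    arm3 = ""
    for link in arm3_ant:
        text = antenna(link, decorations[i])
        arm3 = text if not arm3 else f"{arm3}[{text}]"
        i += 1
    arm6 = ""
    for link in arm6_ant:
        text = antenna(link, decorations[i])
        arm6 = text if not arm6 else f"{arm6}[{text}]"
        i += 1
    arm3 += "Man(a1-3)"
    arm6 += "Man(a1-6)"
    center = f"{arm3}[{arm6}]"
    if bisect:
        center += "[GlcNAc(b1-4)]"
    root = "GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc" if fucose else "GlcNAc(b1-4)GlcNAc"
    return f"{center}Man(b1-4){root}"


def _oxford_count_pos(tok: str) -> tuple[int, str | None]:
    m = re.match(r"^[GS](\d)?(?:\((\d)\))?(\d)?$", tok)
    if not m:
        raise UnsupportedTokenError(tok, "Oxford token")
    count = m.group(1) or m.group(3) or "1"
    return int(count), m.group(2)


# ---------------------------------------------------------------------------
# KCF (KEGG Chemical Function)
# ---------------------------------------------------------------------------


def parse_kcf(s: str) -> str:
    """KCF NODE/EDGE blocks -> raw IUPAC; x/y coordinates order siblings."""
    nodes: dict[int, tuple[str, float, float]] = {}
    edges: list[tuple[int, str, int, str]] = []
    section = None
    for ln in s.splitlines():
        stripped = ln.strip()
        if not stripped or stripped.startswith("///"):
            continue
        head = stripped.split()[0]
        if head in ("ENTRY", "NODE", "EDGE", "BRACKET"):
            section = head
            stripped = stripped[len(head):].strip()
            if not stripped:
                continue
        if section == "NODE" and stripped:
            parts = stripped.split()
            if len(parts) >= 4:
                idx, name, x, y = parts[0], parts[1], parts[2], parts[3]
                nodes[int(idx)] = (name, float(x), float(y))
            continue
        if section == "EDGE" and stripped:
            parts = stripped.split()
            if len(parts) >= 3:
                child_spec, parent_spec = parts[1], parts[2]
                cm = re.match(r"^(\d+)(?::([ab?]?)([12?]?))?$", child_spec)
                pm = re.match(r"^(\d+)(?::([1-9?]+))?$", parent_spec)
                if not cm or not pm:
                    raise GlycanParseError(f"cannot parse KCF edge: {stripped!r}")
                child = int(cm.group(1))
                anomer = cm.group(2) or "?"
                donor = cm.group(3) or "?"
                parent = int(pm.group(1))
                acc = pm.group(2) or "?"
                edges.append((child, f"{anomer}", parent, f"{donor}|{acc}"))
            continue
    if not nodes:
        raise GlycanParseError("KCF input has no NODE block")

    table = ResidueLinkTable()
    for idx, (name, _x, _y) in nodes.items():
        table.residues[idx] = name
    # order sibling edges by the child's y (desc) then x coordinate
    def edge_key(e):
        child = e[0]
        _name, x, y = nodes.get(child, ("", 0.0, 0.0))
        return (-y, x)

    for child, anomer, parent, dacc in sorted(edges, key=edge_key):
        donor, acc = dacc.split("|")
        if child not in nodes or parent not in nodes:
            raise StructureError(f"KCF edge references unknown node {child}->{parent}")
        table.links.append((child, anomer, donor, parent, acc))
    return table.serialize()


# ---------------------------------------------------------------------------
# IUPAC-extended
# ---------------------------------------------------------------------------

_EXT_RESIDUE_RE = re.compile(
    r"(?:([abαβ?])-)?(?:([DL])-)?([A-Z][a-z]{2})([pf])([A-Za-z0-9]*?)"
    r"(?:-\(([12?])(?:→|->)([1-9?])\)-?|$|(?=\[|\]))"
)


def parse_iupac_extended(s: str) -> str:
    """IUPAC-extended (``β-D-Galp-(1→4)-D-Glcp``) -> raw IUPAC string."""
    s = re.sub(r"\s+", "", s.strip())
    out = []
    pos = 0
    for m in _EXT_RESIDUE_RE.finditer(s):
        if m.start() > pos:
            out.append(s[pos : m.start()])  # pass brackets through
        anomer, en, stem, ring, suffix, donor, acc = m.groups()
        anomer = {"α": "a", "β": "b", None: "?"}.get(anomer, anomer)
        token = stem + ("f" if ring == "f" else "") + (suffix or "")
        if en:
            token = f"{en}-{token}"
        out.append(token)
        if donor:
            out.append(f"({anomer}{donor}-{acc})")
        pos = m.end()
    if pos == 0:
        raise UnsupportedTokenError(s, "IUPAC-extended residue")
    out.append(s[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# GlycoWorkbench (GWS)
# ---------------------------------------------------------------------------

_GWS_SEG_RE = re.compile(
    r"--([1-9?])([ab?])([12?])([DL?])-([A-Za-z0-9]+),([pf?])"
)


def parse_gws(s: str) -> str:
    """GlycoWorkbench strings -> raw IUPAC.

    Residues chain outward from the reducing end (``freeEnd--...``);
    parenthesized sub-chains are branches of the residue they follow.
    The trailing ``$MONO...`` block is ignored.
    """
    s = s.strip()
    s = s.split("$")[0]
    for prefix in ("freeEnd", "redEnd"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    table = ResidueLinkTable()
    counter = 0
    current: int | None = None
    stack: list[int | None] = []
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch == "(":
            stack.append(current)
            i += 1
            continue
        if ch == ")":
            if not stack:
                raise GlycanParseError(f"unbalanced ')' in GWS string at {i}")
            current = stack.pop()
            i += 1
            continue
        m = _GWS_SEG_RE.match(s, i)
        if not m:
            raise GlycanParseError(f"malformed GWS residue segment at index {i}: {s[i:i+20]!r}")
        acc, anomer, donor, _en, name, _ring = m.groups()
        idx = counter
        counter += 1
        table.residues[idx] = name
        if current is not None:
            table.links.append((idx, anomer, donor, current, acc))
        current = idx
        i = m.end()
    if not table.residues:
        raise GlycanParseError("GWS string contains no residues")
    return table.serialize()
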