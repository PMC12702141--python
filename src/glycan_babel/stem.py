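"""Common stem: homogenize any IUPAC-like string into standard IUPAC-condensed.

Every input — whether typed by a user in some dialect (CarbBank, CSDB-linear,
dashless linkages, Greek letters, parenthesized branches ...) or emitted by
one of the rudimentary format parsers — passes through the same ordered
stages:

    tokens -> linkages/brackets -> modifications/floating

followed by a parse to a :class:`~glycan_babel.model.GlycanTree`, a chemical
feasibility repair (impossible acceptor assignments become wildcards, never
errors) and re-serialization.  Sibling order is preserved here; deterministic
branch ordering is a separate, later step.

The token synonym table lives in ``data/normalization_rules.json`` so dialect
additions are data changes.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .errors import GlycanParseError
from .model import (
    GlycanTree,
    Linkage,
    Monosaccharide,
    Node,
    SIALIC_BASES,
    check_brackets,
    donor_default,
    parse_iupac_to_tree,
    tree_to_string,
)

_DATA = Path(__file__).parent / "data"
_RULES = json.loads((_DATA / "normalization_rules.json").read_text(encoding="utf-8"))

_MOD_TAG_ALT = "PCho|PEtn|Me|Ac|S|P"


def _parsable(token: str) -> bool:
    return not Monosaccharide.from_token(token, strict=False).unknown


def _strip_ring_p(run: str) -> str:
    """Remove an explicit pyranose 'p' if that yields a known token.

    ``Glcp -> Glc``, ``GlcpNAc -> GlcNAc``, ``Neup5Ac -> Neu5Ac``.  Explicit
    furanose 'f' is part of the canonical token and left alone.
    """
    if _parsable(run):
        return run
    for i in range(len(run) - 1, 0, -1):
        if run[i] == "p":
            cand = run[:i] + run[i + 1 :]
            if _parsable(cand):
                return cand
    return run


def _trailing_residue(s: str) -> str | None:
    """The maximal residue-looking run at the end of ``s``, if parsable."""
    m = re.search(r"((?:[DL]-)?[A-Za-z][A-Za-z0-9]*)$", s)
    if m and _parsable(m.group(1)):
        return m.group(1)
    return None


def _default_float_linkage(token: str) -> str:
    base = Monosaccharide.from_token(token, strict=False).base_name
    if base in SIALIC_BASES:
        return "a2-?"
    return "?1-?"


# ---------------------------------------------------------------------------
# stage 1: tokens
# ---------------------------------------------------------------------------


def normalize_tokens(s: str) -> str:
    """Character fixes, synonym table, case repair, ring/enantiomer defaults."""
    for src, dst in _RULES["characters"].items():
        s = s.replace(src, dst)
    # whitespace: keep '+' as the floating-part marker, drop the rest
    s = re.sub(r"\s*\+\s*", "+", s)
    s = re.sub(r"\s+", "", s)
    s = s.rstrip(";")

    # case repair of whole alphanumeric runs that match a known token
    lowermap = {b.lower(): b for b in _KNOWN_CASE_TOKENS}
    s = re.sub(
        r"[A-Za-z][A-Za-z0-9]*",
        lambda m: lowermap.get(m.group(0).lower(), m.group(0)),
        s,
    )
    # synonym table (boundary-guarded; a/b/f may follow as anomer/ring)
    for src, dst in _RULES["synonyms"].items():
        s = re.sub(rf"(?<![A-Za-z]){re.escape(src)}(?![c-eg-z])", dst, s)

    # D-/L- prefixed full forms: drop default enantiomer and explicit 'p'
    def _fix_dl(m: re.Match) -> str:
        en, rest = m.group(1), m.group(2)
        tok = _strip_ring_p(rest)
        if not _parsable(tok):
            return m.group(0)
        full = Monosaccharide.from_token(f"{en}-{tok}", strict=False)
        return full.to_token()

    s = re.sub(r"(?<![A-Za-z])([DL])-([A-Za-z][A-Za-z0-9]*)", _fix_dl, s)

    # bare explicit-pyranose tokens: Glcp -> Glc (furanose 'f' is canonical)
    s = re.sub(
        r"[A-Za-z][A-Za-z0-9]*",
        lambda m: _strip_ring_p(m.group(0)),
        s,
    )
    return s


_KNOWN_CASE_TOKENS = None  # populated below (after NAMESPACE import resolves)


def _build_case_tokens():
    from .model import NAMESPACE

    toks = set(NAMESPACE)
    toks |= set(_RULES["synonyms"])
    return toks


_KNOWN_CASE_TOKENS = _build_case_tokens()


# ---------------------------------------------------------------------------
# stage 2: linkages and brackets
# ---------------------------------------------------------------------------

_LINKAGE_CONTENT = re.compile(r"^[ab?]?[12?]?-?[1-9?](?:/[1-9])*$|^[ab?][12?]-\?$")


def _fold_csdb(s: str) -> str:
    """Fold CSDB-linear style residues: ``bDGalp(1-4)bDGlcp`` -> IUPAC."""

    def _mid(m: re.Match) -> str:
        anomer, en, name, d, acc = m.groups()
        tok = _strip_ring_p(name)
        if not _parsable(tok):
            return m.group(0)
        mono = Monosaccharide.from_token(f"{en}-{tok}", strict=False)
        return f"{mono.to_token()}({anomer}{d}-{acc})"

    s = re.sub(
        r"(?<![A-Za-z])([ab?])([DL])([A-Z][A-Za-z0-9]*?)\(([12?])-([1-9?])\)",
        _mid,
        s,
    )

    def _terminal(m: re.Match) -> str:
        _anomer, en, name = m.groups()
        tok = _strip_ring_p(name)
        if not _parsable(tok):
            return m.group(0)
        return Monosaccharide.from_token(f"{en}-{tok}", strict=False).to_token()

    s = re.sub(r"(?<![A-Za-z])([ab?])([DL])([A-Z][A-Za-z0-9]*)$", _terminal, s)
    return s


def _parens_to_brackets(s: str) -> str:
    """Parentheses used for branches become square brackets."""
    out = list(s)
    stack: list[int] = []
    for i, ch in enumerate(s):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise GlycanParseError(f"unbalanced ')' at index {i}")
            j = stack.pop()
            inner = s[j + 1 : i]
            if not _LINKAGE_CONTENT.match(inner):
                out[j], out[i] = "[", "]"
    return "".join(out)


def normalize_linkages_and_brackets(s: str) -> str:
    """Standardize linkage spelling and the parenthesis/bracket convention."""
    s = _fold_csdb(s)
    s = re.sub(r"\)-(?=[A-Z{\[])", ")", s)  # dash glued to a linkage close
    s = re.sub(r"-\(", "(", s)  # dash glued to a linkage open
    s = _parens_to_brackets(s)

    def _donor_for(prefix: str) -> str:
        tok = _trailing_residue(prefix)
        if tok is None:
            return "1"
        base = Monosaccharide.from_token(tok, strict=False).base_name
        d = donor_default(base)
        return d if d != "?" else "1"

    # dashed but unparenthesized: Galb1-4Glc -> Gal(b1-4)Glc
    s = re.sub(
        r"(?<![(/])([ab?])([12])-([1-9?](?:/[1-9])*)",
        lambda m: f"({m.group(1)}{m.group(2)}-{m.group(3)})",
        s,
    )
    # dashless: Galb4Glc -> Gal(b1-4)Glc (donor defaulted per residue class)
    s = re.sub(
        r"([ab?])([1-9](?:/[1-9])*)(?=[A-Z\[{])",
        lambda m: f"({m.group(1)}{_donor_for(s[: m.start()])}-{m.group(2)})",
        s,
    )
    # anomer+donor with dash but no position: Mana1-Man -> Man(a1-?)Man
    s = re.sub(
        r"(?<![(/])([ab?])([12])-(?=[A-Z{\[])",
        lambda m: (
            f"({m.group(1)}{m.group(2)}-?)"
            if _trailing_residue(s[: m.start()]) is not None
            else m.group(0)
        ),
        s,
    )
    # anomer with dash but no position: Mana-Man -> Man(a1-?)Man
    s = re.sub(
        r"([ab?])-(?=[A-Z{\[])",
        lambda m: (
            f"({m.group(1)}{_donor_for(s[: m.start()])}-?)"
            if _trailing_residue(s[: m.start()]) is not None
            else m.group(0)
        ),
        s,
    )
    # bare dash between residues: Man-Man -> Man(?1-?)Man
    s = re.sub(
        r"-(?=[A-Z{\[])",
        lambda m: (
            f"(?{_donor_for(s[: m.start()])}-?)"
            if _trailing_residue(s[: m.start()]) is not None
            else m.group(0)
        ),
        s,
    )
    # residue directly against a bracket: Man[ -> Man(?1-?)[ ; [Fuc] -> [Fuc(?1-?)]
    s = re.sub(
        r"(?<=[A-Za-z0-9])(?=[\[\]])",
        lambda m: (
            f"(?{_donor_for(s[: m.start()])}-?)"
            if _trailing_residue(s[: m.start()]) is not None
            else ""
        ),
        s,
    )
    # trailing reducing-end anomer (LinearCode style "...GNb"): drop it
    m = re.search(r"([ab?])([12]?)$", s)
    if m and m.group(0):
        head = s[: m.start()]
        if not _parsable(s[m.start() - _tail_run_len(s, m.start()) : ]) and _trailing_residue(head):
            s = head
    # two residues glued together with no linkage at all: Man(?1-?)Man
    s = _split_glued_residues(s)
    return s


def _tail_run_len(s: str, end: int) -> int:
    i = end
    while i > 0 and (s[i - 1].isalnum()):
        i -= 1
    return end - i


def _split_glued_residues(s: str) -> str:
    while True:
        replaced = False
        for m in re.finditer(r"(?<=[a-z])(?=[A-Z])", s):
            i = m.start()
            left_start = i - _tail_run_len(s, i)
            left = s[left_start:i]
            right = re.match(r"[A-Za-z][A-Za-z0-9]*", s[i:])
            if not right:
                continue
            if not _parsable(left):
                continue
            # the right-hand run must itself start a known residue
            from .model import _BASES_BY_LENGTH  # local import to avoid cycle noise

            if not any(right.group(0).startswith(b) for b in _BASES_BY_LENGTH):
                continue
            base = Monosaccharide.from_token(left, strict=False).base_name
            d = donor_default(base)
            s = s[:i] + f"(?{d if d != '?' else '1'}-?)" + s[i:]
            replaced = True
            break
        if not replaced:
            return s


# ---------------------------------------------------------------------------
# stage 3: modifications and floating substituents
# ---------------------------------------------------------------------------


def normalize_modifications_and_floating(s: str) -> str:
    """Fold modification dialects into tokens; floating parts into ``{...}``."""

    # [4S]Gal -> Gal4S ; [S]Gal -> GalOS
    def _bracket_mod(m: re.Match) -> str:
        pos, tag, token = m.groups()
        if not _parsable(token):
            return m.group(0)
        return f"{token}{pos or 'O'}{tag}"

    s = re.sub(
        rf"\[([1-9]?)({_MOD_TAG_ALT})\]((?:[DL]-)?[A-Z][A-Za-z0-9]*)",
        _bracket_mod,
        s,
    )

    # SGal / S-Gal -> GalOS
    def _prefix_mod(m: re.Match) -> str:
        tag, token = m.groups()
        if not _parsable(token):
            return m.group(0)
        return f"{token}O{tag}"

    s = re.sub(
        rf"(?<![A-Za-z0-9])({_MOD_TAG_ALT})-?((?:[DL]-)?[A-Z][a-z][A-Za-z0-9]*)",
        _prefix_mod,
        s,
    )

    # "Gal?S" (from "Gal? S") -> GalOS
    s = re.sub(
        rf"(?<=[A-Za-z0-9])\?(?={_MOD_TAG_ALT})",
        "O",
        s,
    )

    # "+Neu5Ac" suffix dialects -> "{Neu5Ac(a2-?)}" prefix
    parts = _split_top_level_plus(s)
    if len(parts) > 1:
        main, floats = parts[0], parts[1:]
        rendered = []
        for f in floats:
            if not f:
                continue
            if f.endswith(")"):
                rendered.append("{" + f + "}")
            else:
                tok = _trailing_residue(f) or f
                rendered.append("{" + f + f"({_default_float_linkage(tok)})" + "}")
        s = "".join(sorted(rendered)) + main

    # braced floating part without linkage: {Neu5Ac} -> {Neu5Ac(a2-?)}
    def _brace(m: re.Match) -> str:
        content = m.group(1)
        if content.endswith(")"):
            return m.group(0)
        tok = _trailing_residue(content) or content
        return "{" + content + f"({_default_float_linkage(tok)})" + "}"

    s = re.sub(r"\{([^{}]*)\}", _brace, s)
    return s


def _split_top_level_plus(s: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in s:
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth -= 1
        if ch == "+" and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


# ---------------------------------------------------------------------------
# chemical feasibility
# ---------------------------------------------------------------------------


def enforce_chemical_feasibility(t: GlycanTree) -> GlycanTree:
    """Repair impossible acceptor assignments by wildcarding them.

    For each parent an occupancy map is built from the residue's blocked
    positions (anomeric carbon, ring-oxygen carbon, modifications, class
    constraints) plus sibling linkages already granted; any violating
    integer acceptor becomes ``?``.  Repairs, never rejects; the later
    sibling in reading order is the one wildcarded on duplicates.
    """
    t = t.copy()
    for node in t.nodes():
        blocked = node.residue.blocked_positions()
        maxc = node.residue.max_carbon
        used: set[int] = set()
        fixed: list[tuple[Node, Linkage]] = []
        for child, link in node.children:
            accs = link.acceptors
            if len(accs) == 1 and accs[0] != "?":
                a = int(accs[0])
                if a in blocked or a in used or a > maxc:
                    link = Linkage(link.anomer, link.donor, ("?",))
                else:
                    used.add(a)
            fixed.append((child, link))
        node.children = fixed
    return t


# ---------------------------------------------------------------------------
# the stem
# ---------------------------------------------------------------------------


def common_stem(s: str, *, modifications_stage: bool = True) -> str:
    """Full normalization: stages in order, then parse + feasibility repair.

    ``modifications_stage`` exists for regression testing of stage locality
    and is on by default.
    """
    if not s or not s.strip():
        raise GlycanParseError("empty glycan string")
    stage = "tokens"
    try:
        s = normalize_tokens(s)
        stage = "linkages/brackets"
        s = normalize_linkages_and_brackets(s)
        s = normalize_tokens(s)  # folded dialects may re-expose token variants
        if modifications_stage:
            stage = "modifications/floating"
            s = normalize_modifications_and_floating(s)
        stage = "parse"
        check_brackets(s)
        tree = parse_iupac_to_tree(s)
    except GlycanParseError as exc:
        raise GlycanParseError(f"{exc} [common stem stage: {stage}]") from exc
    tree = enforce_chemical_feasibility(tree)
    return tree_to_string(tree)
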