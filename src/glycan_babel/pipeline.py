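"""End-to-end pipeline: detection -> parser -> common stem -> canonical string.

``canonicalize_any`` is the single entry point: it accepts a glycan written
in any supported nomenclature (or a composition, or a trivial name) and
returns the unique canonicalized IUPAC-condensed representation.  The
``rescue_*`` adapters wrap arbitrary functions so that every glycan-string
argument is canonicalized before the function sees it.
"""

from __future__ import annotations

import functools
import random
import re
from dataclasses import dataclass

from .canonicalize import canonicalize_branches
from .composition import canonicalize_composition
from .detection import NomenclatureKind, check_nomenclature, detect, lookup_common_name
from .errors import GlycanError, GlycanParseError
from .model import parse_iupac_to_tree, tree_to_string
from .parsers import (
    parse_glycam,
    parse_glycoct,
    parse_gws,
    parse_iupac_extended,
    parse_kcf,
    parse_linearcode,
    parse_oxford,
    parse_wurcs,
)
from .stem import common_stem

_PARSERS = {
    NomenclatureKind.WURCS: parse_wurcs,
    NomenclatureKind.GLYCOCT: parse_glycoct,
    NomenclatureKind.LINEARCODE: parse_linearcode,
    NomenclatureKind.GLYCAM: parse_glycam,
    NomenclatureKind.OXFORD: parse_oxford,
    NomenclatureKind.KCF: parse_kcf,
    NomenclatureKind.IUPAC_EXTENDED: parse_iupac_extended,
    NomenclatureKind.GWS: parse_gws,
}


def canonicalize_any(s: str) -> str:
    """Convert any supported glycan string to canonical IUPAC-condensed.

    Compositions are routed to the composition handler and returned in
    canonical composition form.  Idempotent and deterministic.
    """
    if not isinstance(s, str) or not s.strip():
        raise GlycanParseError("empty glycan string")
    s = s.strip()
    named = lookup_common_name(s)
    if named is not None:
        s = named
    kind = detect(s)
    if kind == NomenclatureKind.COMPOSITION:
        return canonicalize_composition(s)
    if kind in _PARSERS:
        raw = _PARSERS[kind](s)
    else:
        check_nomenclature(s)  # raises for SMILES & friends
        raw = s
    standardized = common_stem(raw)
    tree = parse_iupac_to_tree(standardized)
    return tree_to_string(canonicalize_branches(tree))


@dataclass
class ConversionRecord:
    """Per-input outcome of a batch conversion."""

    input_text: str
    detected: NomenclatureKind
    canonical: str | None
    status: str  # "ok" | "error"
    message: str = ""


def convert_record(s: str) -> ConversionRecord:
    """Convert one input, capturing errors instead of raising."""
    kind = detect(s)
    try:
        canonical = canonicalize_any(s)
        return ConversionRecord(s, kind, canonical, "ok")
    except GlycanError as exc:
        return ConversionRecord(s, kind, None, "error", str(exc))


# ---------------------------------------------------------------------------
# rescue adapters
# ---------------------------------------------------------------------------


def rescue_adapter(func=None, *, canonicalizer=canonicalize_any):
    """Wrap ``func`` so glycan-string arguments are canonicalized first.

    Every ``str`` argument (and every element of list/tuple-of-str
    arguments) is passed through ``canonicalizer`` before ``func`` runs;
    other arguments are untouched.  Canonicalization failures propagate,
    annotated with the offending argument position.
    """

    def deco(f):
        @functools.wraps(f)
        def wrapper(*args, **kwargs):
            def fix(value, label):
                if isinstance(value, str):
                    try:
                        return canonicalizer(value)
                    except GlycanError as exc:
                        raise type(exc)(f"argument {label}: {exc}") from exc
                if isinstance(value, (list, tuple)) and value and all(
                    isinstance(v, str) for v in value
                ):
                    return type(value)(fix(v, label) for v in value)
                return value

            args = [fix(a, str(i)) for i, a in enumerate(args)]
            kwargs = {k: fix(v, k) for k, v in kwargs.items()}
            return f(*args, **kwargs)

        return wrapper

    return deco(func) if func is not None else deco


def rescue_glycans(func):
    """Decorator: canonicalize every glycan-string argument of ``func``."""
    return rescue_adapter(func, canonicalizer=canonicalize_any)


def rescue_compositions(func):
    """Decorator: canonicalize every composition-string argument of ``func``."""
    return rescue_adapter(func, canonicalizer=canonicalize_composition)


# ---------------------------------------------------------------------------
# dialect-variant generator (powers the fixture corpus)
# ---------------------------------------------------------------------------


def _drop_donor(s: str) -> str:
    # Gal(b1-4) -> Galb4 (the stem re-derives the default donor carbon)
    return re.sub(r"\(([ab])[12]-([1-9])\)", r"\1\2", s) if "[" not in s else s


def _dashless(s: str) -> str:
    return re.sub(r"\(([ab?])([12])-([1-9?])\)", r"\1\2-\3", s) if "[" not in s else s


def _greek(s: str) -> str:
    return s.replace("a", "α").replace("b", "β")


def _synonyms_back(s: str) -> str:
    return s.replace("Neu5Ac", "NeuAc").replace("Neu5Gc", "NeuGc")


def _parens_branches(s: str) -> str:
    return s.replace("[", "(").replace("]", ")")


def _mod_prefix_style(s: str) -> str:
    # Gal6S(...) -> [6S]Gal(...)
    return re.sub(r"((?:[DL]-)?[A-Z][A-Za-z0-9]*?)([1-9])(S|P|Me|Ac)(?=\(|$)", r"[\2\3]\1", s)


def _spaces(s: str, rng: random.Random) -> str:
    i = rng.randrange(1, len(s))
    return s[:i] + " " + s[i:]


def _shuffle_siblings(s: str, rng: random.Random) -> str:
    tree = parse_iupac_to_tree(s)

    def shuffle(node):
        rng.shuffle(node.children)
        for child, _ in node.children:
            shuffle(child)

    shuffle(tree.root)
    return tree_to_string(tree)


def generate_dialect_variants(canonical: str, seed: int, n: int) -> list[str]:
    """Reproducibly emit ``n`` distinct dialect variants of a canonical string.

    Every variant is guaranteed (by construction *and* by a re-canonicalization
    check) to satisfy ``canonicalize_any(variant) == canonical``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    simple = [_greek, _synonyms_back, _dashless, _drop_donor, _parens_branches,
              _mod_prefix_style]
    variants: list[str] = []
    seen = {canonical}
    attempts = 0
    while len(variants) < n and attempts < 200 * n + 200:
        attempts += 1
        v = canonical
        if rng.random() < 0.3 and "[" in canonical:
            v = _shuffle_siblings(v, rng)
        picks = rng.sample(simple, k=rng.randint(1, 3))
        for fn in picks:
            v = fn(v)
        if rng.random() < 0.4:
            v = _spaces(v, rng)
        if v in seen:
            # always-available fallback: whitespace insertion is unbounded
            v = _spaces(v, rng)
        if v in seen:
            continue
        try:
            if canonicalize_any(v) != canonical:
                continue
        except GlycanError:
            continue
        seen.add(v)
        variants.append(v)
    if len(variants) < n:
        raise GlycanError(
            f"could not generate {n} distinct variants for {canonical!r}"
        )
    return variants
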