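"""Nomenclature detection: hooks, common-name dictionary, rejection.

Detection is heuristic by design: a fixed priority order of string hooks
classifies the input; anything matching no hook falls through to
``IUPAC_OR_CSDB`` and is handled by the common stem.  Detection never
raises — unsupported languages are a *value* — while
:func:`check_nomenclature` turns obviously foreign strings (SMILES ...)
into a descriptive error.
"""

from __future__ import annotations

import enum
import json
import re
from pathlib import Path

from .composition import detect_composition
from .errors import GlycanParseError, UnsupportedNomenclatureError

_DATA = Path(__file__).parent / "data"


class NomenclatureKind(enum.Enum):
    WURCS = "WURCS"
    GLYCOCT = "GLYCOCT"
    LINEARCODE = "LINEARCODE"
    GLYCAM = "GLYCAM"
    OXFORD = "OXFORD"
    KCF = "KCF"
    IUPAC_EXTENDED = "IUPAC_EXTENDED"
    GWS = "GWS"
    IUPAC_OR_CSDB = "IUPAC_OR_CSDB"
    COMMON_NAME = "COMMON_NAME"
    COMPOSITION = "COMPOSITION"
    UNSUPPORTED = "UNSUPPORTED"


def _normalize_name_key(s: str) -> str:
    return re.sub(r"\s+", "", s).lower()


def _load_names() -> dict[str, str]:
    raw = json.loads((_DATA / "common_names.json").read_text(encoding="utf-8"))
    return {_normalize_name_key(k): v for k, v in raw["names"].items()}


COMMON_NAMES = _load_names()


def lookup_common_name(s: str) -> str | None:
    """O(1), case- and whitespace-insensitive trivial-name lookup."""
    return COMMON_NAMES.get(_normalize_name_key(s))


# -- hooks ------------------------------------------------------------------

_GLYCOCT_RE = re.compile(r"^RES\s*$", re.M)
_GLYCOCT_LINE_RE = re.compile(r"^\d+[bs]:", re.M)
_GLYCAM_RES_RE = re.compile(r"[DL][A-Z][a-z]{2}[pf]")
_EXT_ARROW_RE = re.compile(r"\(\s*[12?]\s*(?:->|→)\s*[1-9?]\s*\)")
_EXT_NAME_RE = re.compile(r"(?<![A-Za-z])[abαβ?]-[DL]-")
_LINEARCODE_RE = re.compile(r"^[A-Z]{1,2}[ab?][1-9?]")
_OXFORD_RE = re.compile(
    r"^F?(?:A\d|B|G\d(?:\(\d\))?|G\(\d\)\d?|S\d(?:\(\d\))?|S\(\d\)\d?|M\d)+$"
)
_SMILES_STRONG_RE = re.compile(r"[@=#]")
_SMILES_RING_RE = re.compile(r"[CNOcno]\d[CNOcno(]")


def _looks_like_smiles(s: str) -> bool:
    if s.startswith("WURCS"):
        return False
    return bool(_SMILES_STRONG_RE.search(s) or _SMILES_RING_RE.search(s))


def detect(s: str) -> NomenclatureKind:
    """Classify a raw input string; never raises."""
    s = s.strip()
    if not s:
        return NomenclatureKind.UNSUPPORTED
    if lookup_common_name(s) is not None:
        return NomenclatureKind.COMMON_NAME
    # block formats first: their hooks cannot collide with one-liners
    if _GLYCOCT_RE.search(s) and _GLYCOCT_LINE_RE.search(s):
        return NomenclatureKind.GLYCOCT
    if "NODE" in s and "EDGE" in s:
        return NomenclatureKind.KCF
    if s.startswith("WURCS"):
        return NomenclatureKind.WURCS
    if "freeEnd" in s or "redEnd" in s or "$MONO" in s or ("--" in s and ",p" in s):
        return NomenclatureKind.GWS
    if s.upper().endswith(("-OH", "-OME")) and _GLYCAM_RES_RE.search(s):
        return NomenclatureKind.GLYCAM
    if "→" in s or _EXT_ARROW_RE.search(s) or _EXT_NAME_RE.search(s):
        return NomenclatureKind.IUPAC_EXTENDED
    if _LINEARCODE_RE.match(s) and "-" not in s:
        return NomenclatureKind.LINEARCODE
    if _OXFORD_RE.match(s):
        return NomenclatureKind.OXFORD
    if detect_composition(s):
        return NomenclatureKind.COMPOSITION
    if _looks_like_smiles(s):
        return NomenclatureKind.UNSUPPORTED
    return NomenclatureKind.IUPAC_OR_CSDB


def check_nomenclature(s: str) -> None:
    """Reject strings in languages we knowingly do not convert.

    Called for inputs that fell through to IUPAC_OR_CSDB.  Raises
    :class:`UnsupportedNomenclatureError` naming the suspected language.
    """
    if not s or not s.strip():
        raise GlycanParseError("empty input")
    if _looks_like_smiles(s.strip()):
        raise UnsupportedNomenclatureError(
            "input looks like SMILES, which is not a supported glycan "
            "nomenclature (convert it to WURCS/GlycoCT/IUPAC first)"
        )
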