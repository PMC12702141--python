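"""Exception hierarchy shared across the package."""


class GlycanError(Exception):
    """Base class for every error raised by glycan-babel."""


class GlycanParseError(GlycanError):
    """A string could not be parsed into a glycan tree."""


class UnsupportedTokenError(GlycanParseError):
    """A residue/descriptor token is outside the supported vocabulary.

    The offending token is always carried verbatim in ``token``.
    """

    def __init__(self, token: str, context: str = ""):
        self.token = token
        msg = f"unsupported token: {token!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class UnsupportedNomenclatureError(GlycanError):
    """The input is written in a language we deliberately do not convert."""


class StructureError(GlycanError):
    """A residue/link table or graph violates tree-ness."""
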