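"""Exception hierarchy.

All package errors derive from :class:`KmermatchError` so callers can catch
one base class; parameter/input errors additionally derive from the matching
builtin (``ValueError``) for idiomatic use.
"""


class KmermatchError(Exception):
    """Base class for all kmermatch errors."""


class InvalidParameterError(KmermatchError, ValueError):
    """A function argument violates its contract (bad k, wrong length, ...)."""


class InvalidInputError(KmermatchError, ValueError):
    """Input data violates an invariant (empty proteome, bad residue, ...)."""


class InfeasibleParametersError(InvalidParameterError):
    """The (l, m) combination admits no seed size >= 1 — more peptide pieces
    than residues — or the supplied index k breaks pigeonhole completeness."""


class ParseError(InvalidInputError):
    """A file could not be parsed; ``line`` is the 1-based offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StaleIndexError(KmermatchError):
    """A stored index does not match the requested k or proteome checksum."""


class IndexFormatError(KmermatchError):
    """A stored index file is corrupt or not a recognised index container."""
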