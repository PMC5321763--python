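"""Exception hierarchy for poregate.

All package errors derive from :class:`PoregateError` so callers can catch a
single type; subclasses also derive from the closest builtin so generic
handling (``except ValueError``) keeps working.
"""


class PoregateError(Exception):
    """Base class for all poregate errors."""


class ParameterError(PoregateError, ValueError):
    """A parameter value is outside its documented domain."""


class ParseError(PoregateError, ValueError):
    """A file could not be parsed into the expected structure."""


class UnsupportedFormatError(ParseError):
    """The file uses a feature the reader deliberately does not support."""


class SelectionError(PoregateError, LookupError):
    """An atom/residue/chain selection matched nothing; names the criterion."""


class GeometryError(PoregateError, ValueError):
    """Input geometry is degenerate for the requested computation."""


class AlignmentError(PoregateError, ValueError):
    """Two traces/sweeps do not share a common protocol or length."""


class FitError(PoregateError, RuntimeError):
    """A model fit failed to converge or produced a non-physical optimum."""


class UndefinedBlockError(PoregateError, ValueError):
    """Fractional blockade is undefined (control current at the noise floor)."""


class InputError(PoregateError, ValueError):
    """Structured inputs (images, tables) are inconsistent."""
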