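"""Exception hierarchy shared across the package."""


class OligomerkitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OligomerkitError, ValueError):
    """A physically or numerically invalid input (negative density, FRET > 1, ...)."""


class UndefinedOperationError(OligomerkitError, ValueError):
    """The requested quantity is undefined for the given model (e.g. half-saturation of a monomer)."""


class InsufficientDataError(OligomerkitError, ValueError):
    """Not enough records/frames to perform the computation."""


class SchemaError(OligomerkitError, ValueError):
    """A delimited-text input is missing required columns or contains malformed rows."""


class EmptyStructureError(OligomerkitError, ValueError):
    """A structure file yielded no usable atom records."""


class NumericalDegeneracyError(OligomerkitError, ValueError):
    """Geometry too degenerate for the requested numerical operation."""
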