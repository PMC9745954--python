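"""Exception hierarchy.

Every error raised by fueldry derives from :class:`FuelDryError`, so callers
can catch one base class.  Input-validation failures additionally derive from
``ValueError`` to behave well in generic numeric code.
"""


class FuelDryError(Exception):
    """Base class for all fueldry errors."""


class InvalidInputError(FuelDryError, ValueError):
    """An argument violates a precondition (sign, range, shape, length)."""


class InvalidParameterError(InvalidInputError):
    """A model parameter set is physically or mathematically invalid."""


class NoCrossingError(FuelDryError):
    """A drying curve never reaches the requested moisture level."""


class GridMismatchError(InvalidInputError):
    """Curves that must share a time grid do not."""


class DegenerateFitError(FuelDryError):
    """The data carry no signal the model could fit (e.g. a flat series)."""


class ConvergenceError(FuelDryError):
    """Nonlinear least squares failed to converge; diagnostics in args."""


class FoldSizeError(InvalidInputError):
    """A cross-validation fold leaves too few training points for a fit."""


class FormatError(FuelDryError):
    """A curve file is malformed; the message reports offending line numbers."""
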