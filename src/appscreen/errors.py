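"""Exception hierarchy for the screen-analysis pipeline.

Errors are grouped so callers (and the CLI) can distinguish bad input
from a stage failing on valid input.
"""


class AppScreenError(Exception):
    """Base class for all package errors."""


class InputError(AppScreenError, ValueError):
    """Invalid parameters or malformed input data."""


class PlacementError(AppScreenError):
    """Could not place the requested number of cells without overlap."""


class CellOutOfBoundsError(InputError):
    """A cell footprint does not fit inside the image bounds."""


class CapacityError(InputError):
    """More perturbations than available sample wells."""


class SSMDUndefinedError(AppScreenError):
    """Both groups have zero variance; the SSMD denominator is zero."""


class QCError(AppScreenError):
    """A plate is missing a control group required for quality control."""


class NormalizationError(AppScreenError):
    """No usable non-targeting wells on a plate that has sample wells."""


class SizingError(InputError):
    """Too few scored genes for the requested tail fraction."""


class FixtureFormatError(InputError):
    """A packaged or user-supplied table failed validation."""
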