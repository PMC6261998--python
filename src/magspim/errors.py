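"""Exception hierarchy shared across the package."""


class MagspimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MagspimError, ValueError):
    """A function argument violates its documented precondition."""


class InvalidInputError(MagspimError, ValueError):
    """Input data (stack, mask, config) is malformed or inconsistent."""


class BoundaryNotFoundError(MagspimError):
    """No stack plane exceeds the Otsu boundary threshold."""


class NoFieldError(MagspimError):
    """All magnet currents are zero: no field direction is defined."""


class DegenerateFieldError(MagspimError):
    """Current-weighted sum of magnet directions is the zero vector."""


class InsufficientDataError(MagspimError):
    """Too few usable observations for a fit."""


class ConfigError(MagspimError):
    """Experiment configuration failed validation."""
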