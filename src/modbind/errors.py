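"""Exception hierarchy shared across the package."""


class ModBindError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ModBindError, ValueError):
    """A physical parameter is outside its admissible range."""


class InvalidInputError(ModBindError, ValueError):
    """Input data violate a documented precondition."""


class DegenerateRangeError(InvalidInputError):
    """A normalization range collapses to a point."""


class ConfigValidationError(ModBindError, ValueError):
    """A run configuration failed validation; message lists offending keys."""


class StructureFileError(ModBindError, ValueError):
    """A structure file is missing required records or is malformed."""


class TrajectoryFormatError(ModBindError, ValueError):
    """A trajectory file cannot be read or does not match its topology."""


class UnstableTimestepError(InvalidParameterError):
    """Integrator time step violates the stability bound for the potential."""


class UnreliableEstimateError(ModBindError, RuntimeError):
    """A k_off estimate was requested from a lower-bound-only median."""
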