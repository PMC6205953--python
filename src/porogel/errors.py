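"""Exception hierarchy shared across porogel modules."""


class PorogelError(Exception):
    """Base class for all porogel-specific errors."""


class ValidationError(PorogelError, ValueError):
    """A domain object or argument violates its invariants."""


class KinematicsError(ValidationError):
    """A stretch or volume ratio is outside the physically admissible range."""


class IncompressibleLimitError(ValidationError):
    """nu -> 0.5: the drained bulk modulus is undefined."""


class ConfigError(PorogelError, ValueError):
    """A run configuration file failed to parse or validate."""


class SolverError(PorogelError, RuntimeError):
    """The implicit consolidation solver failed to converge."""


class ConstitutiveInstabilityError(SolverError):
    """A non-positive constitutive tangent was met inside the working range."""
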