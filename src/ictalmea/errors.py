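"""Exception types shared across the package."""


class IctalMEAError(Exception):
    """Base class for package-specific errors."""


class FormatError(IctalMEAError):
    """A file does not conform to the expected container layout."""


class ConsistencyError(IctalMEAError):
    """Metadata and data disagree (e.g., channel count vs electrode layout)."""


class ConfigError(IctalMEAError, ValueError):
    """An invalid configuration value or combination."""


class DecompositionError(IctalMEAError):
    """Source separation cannot proceed (e.g., rank-deficient input)."""


class EstimationError(IctalMEAError):
    """A quantity cannot be estimated from the given data."""


class DomainError(IctalMEAError, ValueError):
    """A requested inversion has no solution in the physical domain."""
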