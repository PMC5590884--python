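"""Exception hierarchy.

Three families map onto the CLI exit statuses: parameter/config misuse (exit 2),
problems with the data itself (exit 3), and anything else (internal failure, exit 1).
"""


class GaitDfaError(Exception):
    """Base class for all package errors."""


class ParameterError(GaitDfaError, ValueError):
    """An argument or configuration value is out of its valid range."""


class ConfigError(ParameterError):
    """A run configuration file could not be parsed or validated."""


class DataError(GaitDfaError):
    """Input data violates the cohort/feature contracts."""


class CohortError(DataError):
    """Manifest or trial files are malformed, inconsistent or incomplete."""


class EventDetectionError(DataError):
    """No usable stance phase / gait cycle could be located in a GRF signal."""
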