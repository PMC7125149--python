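"""Exception hierarchy.

Validation errors (bad inputs, malformed files, infeasible configurations)
are distinguished from runtime errors so the CLI can map them to exit code 2.
"""


class PolystateError(Exception):
    """Base class for all package errors."""


class ValidationError(PolystateError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValidationError):
    """Infeasible or contradictory configuration parameters."""
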