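"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (config 2, input 3, numerical 4).
"""


class ChcevolError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ChcevolError):
    """Invalid or inconsistent configuration."""


class InvalidInputError(ChcevolError):
    """Malformed or degenerate input data."""


class NumericalError(ChcevolError):
    """A numerical procedure failed (singularity, non-convergence)."""
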