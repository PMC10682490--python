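"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes (config 2, data 3, numerical 4).
"""


class ConngradError(Exception):
    """Base class for all package errors."""


class ConfigError(ConngradError):
    """Invalid configuration or parameterization."""


class DataError(ConngradError):
    """Malformed, inconsistent, or insufficient input data."""


class NumericalError(ConngradError):
    """A computation is undefined or unstable for the given input."""
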