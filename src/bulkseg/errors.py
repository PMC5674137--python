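"""Exception hierarchy shared across the package."""


class BulksegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BulksegError):
    """Invalid configuration: missing sample names, bad parameter values, unknown formats."""


class DataError(BulksegError):
    """Malformed or inconsistent input data."""


class EmptyInputError(DataError):
    """An input that yielded no usable records."""
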