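"""Exception hierarchy shared across the pipeline."""


class IcnPipeError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(IcnPipeError, ValueError):
    """A parameter combination that can never produce a valid result."""


class InvalidInputError(IcnPipeError, ValueError):
    """Data handed to an operation violates its preconditions."""


class SchemaError(IcnPipeError, ValueError):
    """A tabular input is missing columns or contains illegal values."""


class FormatError(IcnPipeError, ValueError):
    """A file on disk could not be parsed as the expected format."""


class UndefinedMetricError(IcnPipeError, ValueError):
    """A performance metric is undefined for the given label set."""
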