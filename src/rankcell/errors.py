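"""Exception hierarchy shared across the pipeline.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` (and subclasses) to exit code 3.
"""


class RankcellError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RankcellError):
    """Invalid configuration: bad dimensions, overlapping programs, ..."""


class DataError(RankcellError):
    """Invalid or inconsistent input data."""


class GenerationError(DataError):
    """A requested synthetic construct cannot be realized."""
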