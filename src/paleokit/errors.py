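"""Exception hierarchy."""


class PaleokitError(Exception):
    """Base class for all package errors."""


class FormatError(PaleokitError):
    """A file does not conform to its declared format."""


class DataError(PaleokitError):
    """Input is well-formed but internally inconsistent."""


class ParameterError(PaleokitError, ValueError):
    """A parameter violates its contract."""
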