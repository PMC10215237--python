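"""Exception hierarchy shared across the package.

Validation-type errors (bad schema, bad parameters, inconsistent inputs)
map to CLI exit code 2; runtime/numerical errors map to exit code 3.
"""


class MsnetpharmError(Exception):
    """Base class for all package errors."""


class SchemaError(MsnetpharmError):
    """An input file is missing required columns or uses unknown labels."""


class ValidationError(MsnetpharmError):
    """Inputs are structurally invalid or mutually inconsistent."""


class ParameterError(MsnetpharmError):
    """A configuration or scenario parameter is out of its valid range."""


class GenerationError(MsnetpharmError):
    """The synthetic generator cannot satisfy the requested scenario."""


class NumericalError(MsnetpharmError):
    """A linear solve or iteration failed for numerical reasons."""
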