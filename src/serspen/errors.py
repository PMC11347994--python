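"""Exception hierarchy.

All argument/contract violations raise :class:`DomainError` (a ValueError),
malformed files raise :class:`FormatError`, and inputs that are formally valid
but carry no usable signal raise :class:`DegenerateInputError`.
"""


class SerspenError(Exception):
    """Base class for all package errors."""


class DomainError(SerspenError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SerspenError, ValueError):
    """A file or sidecar does not match the documented container layout."""


class DegenerateInputError(SerspenError, ValueError):
    """Input is structurally valid but degenerate (e.g. all pixels identical)."""


class EmptyDatasetError(SerspenError, ValueError):
    """A curation or filtering step retained no spectra."""


class ConfigError(SerspenError, ValueError):
    """A pipeline configuration file fails schema validation."""
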