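"""Exception hierarchy used across the pipeline."""


class PipeqtlError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PipeqtlError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class DesignError(PipeqtlError, ValueError):
    """A model design matrix is unusable (rank deficiency, missing factor cell,
    mismatched observation sets)."""


class EstimationError(PipeqtlError, RuntimeError):
    """An estimation step cannot proceed (degenerate data, no markers left,
    too few lines)."""


class UnknownIdentifierError(PipeqtlError, KeyError):
    """A marker, gene, trait or line id is not present in the data."""
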