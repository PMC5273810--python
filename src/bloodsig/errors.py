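"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PipelineError):
    """Malformed or inconsistent input data (user error)."""


class ConfigurationError(PipelineError):
    """Impossible or out-of-range configuration (user error)."""


class FormatError(ValidationError):
    """A file does not conform to its declared dialect."""
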