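"""Exception types shared across the pipeline."""


class CentrotimeError(Exception):
    """Base class for all package errors."""


class SizingError(CentrotimeError, ValueError):
    """A genome / interval dimension is impossible (e.g. centromere > chromosome)."""


class ModeError(CentrotimeError, ValueError):
    """An operation was invoked in a mode its input cannot support."""


class ConfigError(CentrotimeError, ValueError):
    """A configuration value is missing or malformed."""


class PipelineError(CentrotimeError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. no usable reads)."""
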