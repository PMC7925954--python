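"""Exception types shared across the pipeline."""


class SigRecoverError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigRecoverError):
    """A configuration value is missing, malformed, or out of range.

    The message always names the offending field.
    """


class DataError(SigRecoverError):
    """Input data violates a structural precondition (e.g. an all-zero sample)."""


class PipelineError(SigRecoverError):
    """A pipeline stage failed; the message names the stage."""


class UndefinedStatisticError(SigRecoverError):
    """A statistic is undefined for the given input (e.g. zero-variance correlation)."""
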