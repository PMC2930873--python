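"""Exception hierarchy shared across the package."""


class GenactivError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GenactivError, ValueError):
    """Invalid configuration value (frequency out of range, bad proportions, ...)."""


class DataError(GenactivError, ValueError):
    """Malformed or inconsistent input data (parse errors, schema mismatches)."""


class VocabularyError(DataError):
    """A categorical value outside the declared vocabulary."""


class ModelError(GenactivError, RuntimeError):
    """Model fitting failure (rank deficiency, separation, non-convergence)."""


class PipelineError(GenactivError, RuntimeError):
    """A pipeline stage failed; carries the stage name in the message."""
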