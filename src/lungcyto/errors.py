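"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so that configuration
mistakes, bad data and missing upstream stage outputs are
distinguishable in batch runs.
"""


class LungCytoError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LungCytoError):
    """Invalid parameter values or incompatible configuration."""


class FormatError(LungCytoError):
    """Unsupported image format (wrong channel count, dtype, shape)."""


class InputError(LungCytoError):
    """Operation applied to invalid input data (empty image, shape mismatch)."""


class DataError(LungCytoError):
    """Dataset-level problems: unknown labels, missing files, empty sets."""


class InsufficientDataError(DataError):
    """A class has fewer rows than an operation requires."""


class DependencyError(LungCytoError):
    """A pipeline stage was requested before its upstream stage ran."""


class StatisticsError(LungCytoError):
    """Summary statistics requested on too few values."""
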