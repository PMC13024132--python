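"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`QeegError` so the orchestrator can
attach the stage name when propagating.
"""


class QeegError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(QeegError):
    """Invalid configuration (unknown electrode, missing region, bad spec)."""


class ValidationError(QeegError):
    """Invalid data values (negative power, non-finite samples)."""


class MontageError(QeegError):
    """Required electrodes absent from a recording."""


class FormatError(QeegError):
    """Unparseable input file."""


class DurationError(QeegError):
    """Retained recording shorter than the configured minimum."""


class ParameterError(QeegError):
    """Invalid numeric parameter (filter corners, window sizes, lags)."""


class DataError(QeegError):
    """Non-finite or otherwise unusable samples."""


class EstimatorError(QeegError):
    """An estimator cannot be computed from the given inputs."""


class DefinitionError(QeegError):
    """A regional/metric definition cannot be evaluated (missing channel)."""


class FitError(QeegError):
    """A regression or optimisation failed (rank deficiency, no minimum)."""


class DesignError(QeegError):
    """Statistical design mismatch (paired groups of unequal size)."""
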