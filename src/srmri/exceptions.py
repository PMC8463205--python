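"""Exception hierarchy.

All configuration/shape problems raise subclasses of :class:`SrmriError`
so callers can catch package errors without masking programming bugs.
"""


class SrmriError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SrmriError, ValueError):
    """An option, hyperparameter, or identifier is invalid."""


class ShapeError(SrmriError, ValueError):
    """Array dimensions are incompatible with the requested operation."""


class DegenerateInputError(SrmriError, ValueError):
    """Input is formally valid but mathematically degenerate (e.g. an
    all-zero image passed to max-normalization, or a contingency table
    with a zero marginal)."""


class TrainingError(SrmriError, RuntimeError):
    """Training failed, e.g. the loss became non-finite."""
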