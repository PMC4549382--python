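"""Exception hierarchy shared across the pipeline."""


class OrsegError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(OrsegError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateFitError(OrsegError, RuntimeError):
    """A model fit is undefined for the given data (no signal / no variance)."""


class DelineationError(OrsegError, RuntimeError):
    """Visual-area delineation failed (e.g. no polar-angle reversals found)."""


class IncompleteDesignError(OrsegError, ValueError):
    """A repeated-measures design is missing cells."""


class UndefinedPercentageError(OrsegError, ZeroDivisionError):
    """Percentages are undefined because the relevant total count is zero."""
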