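"""Exception hierarchy.

Every error raised by the package derives from :class:`CyclosimError` so
callers can catch the package's failures with a single ``except`` clause.
"""


class CyclosimError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CyclosimError, ValueError):
    """A value violates a documented precondition (negative concentration, ...)."""


class StructuralError(CyclosimError):
    """Model/state shape mismatch or an inconsistent model graph."""


class NoSteadyStateError(CyclosimError):
    """Synthesis exceeds maximal hydrolysis capacity; no finite steady state."""


class ConvergenceError(CyclosimError):
    """A numerical solver failed to converge; carries diagnostics in args."""


class IncompatibleTreatmentError(CyclosimError):
    """A drug was applied to a model of the wrong nucleotide."""


class InvalidProtocolError(CyclosimError):
    """Protocol events are out of order, duplicated or out of range."""


class CorruptFrameError(CyclosimError):
    """A fluorescence frame has non-positive background-subtracted intensity."""

    def __init__(self, frame: int, message: str | None = None):
        self.frame = frame
        super().__init__(message or f"corrupt frame {frame}: non-positive background-subtracted intensity")


class InsufficientBaselineError(CyclosimError):
    """Fewer than the required pre-stimulus frames are available."""


class NoPlateauError(CyclosimError):
    """No post-event window satisfied the plateau (flat-slope) criterion."""


class MissingEventError(CyclosimError):
    """A required event label is absent from the trace."""


class CalibrationError(CyclosimError):
    """Dynamic-range calibration produced r_max <= r_min."""


class OutOfRangeError(CyclosimError, ValueError):
    """A ratio lies outside the sensor's open dynamic range (r_min, r_max)."""


class IdentifiabilityError(CyclosimError):
    """The fitting problem is underdetermined; ``params`` lists the unconstrained ones."""

    def __init__(self, params, message: str | None = None):
        self.params = list(params)
        super().__init__(message or f"underdetermined fit; unconstrained parameters: {self.params}")


class MissingDataError(CyclosimError):
    """A dataset directory is empty or incomplete."""


class ConfigError(CyclosimError):
    """A configuration file or mapping violates its schema."""
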