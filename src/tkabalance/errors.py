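"""Exception hierarchy shared across the pipeline."""


class TkaError(Exception):
    """Base class for all package errors."""


class ParameterError(TkaError, ValueError):
    """A scalar argument is outside its admissible domain."""


class DegenerateInputError(TkaError, ValueError):
    """Input geometry is degenerate for the requested fit (coplanar,
    collinear, or too few points)."""


class FitFailureError(TkaError, RuntimeError):
    """An iterative fit did not converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class GeometryError(TkaError, ValueError):
    """A geometric construction is ill-defined (e.g. zero-length line of
    action)."""


class InfeasibleFrameError(TkaError, RuntimeError):
    """Static optimization could not balance a coordinate at one frame."""

    def __init__(self, message, coordinate=None, frame=None):
        super().__init__(message)
        self.coordinate = coordinate
        self.frame = frame
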