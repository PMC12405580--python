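"""Exception hierarchy shared across the package."""


class AccommodateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AccommodateError):
    """A coordinate file does not parse under the named standard."""


class IntegrityError(AccommodateError):
    """Inconsistent internal state: duplicate atom keys, mismatched rosters,
    indices referencing non-existent atoms."""


class ResolutionError(AccommodateError):
    """An atom specification resolves to zero or more than one atom."""


class ParameterError(AccommodateError, ValueError):
    """A parameter is outside its valid domain."""


class GeometryError(AccommodateError):
    """Coordinates do not admit the requested measurement (zero-length bond,
    collinear plane atoms, ...)."""


class SingularityError(AccommodateError):
    """Overlapping atoms make a 1/r term undefined."""


class InstabilityError(AccommodateError):
    """The integrator diverged.  Carries the step at which it happened."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class FitError(AccommodateError):
    """Nonlinear fit failed to converge.  Carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NoEventsError(AccommodateError):
    """A rate/barrier estimate was requested with zero recorded events."""
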