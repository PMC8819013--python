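"""Exception hierarchy shared across the package."""


class BlinktrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BlinktrackError, ValueError):
    """A parameter violates a documented precondition."""


class NoDiffractionError(BlinktrackError, ValueError):
    """The requested reflection is unreachable at the given wavelength."""


class OutOfGeometryError(BlinktrackError, ValueError):
    """An angle cannot be mapped onto the (flat, normal-incidence) detector."""


class EmptySelectionError(BlinktrackError, ValueError):
    """A ring mask selects no detector pixels."""


class ConfigurationError(BlinktrackError, ValueError):
    """Mutually inconsistent objects were combined (geometry/ring/movie)."""


class UndefinedAcfError(BlinktrackError, ValueError):
    """The autocorrelation is undefined (zero-mean trace)."""


class EmptyResultError(BlinktrackError, RuntimeError):
    """An analysis produced no accepted results.

    Carries a per-condition rejection tally in ``tally``.
    """

    def __init__(self, message: str, tally: dict | None = None):
        super().__init__(message)
        self.tally = dict(tally or {})


class InvalidTrajectoryError(BlinktrackError, ValueError):
    """A trajectory leaves the detector bounds."""


class EmptySampleError(BlinktrackError, ValueError):
    """No displacement samples could be formed at the requested lag."""


class DegenerateTestError(BlinktrackError, ValueError):
    """A two-sample test cannot be computed (zero variance everywhere)."""


class FormatError(BlinktrackError, ValueError):
    """An on-disk artifact is malformed."""
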