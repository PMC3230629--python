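"""Exception hierarchy for fluxcomp.

All errors raised by the package derive from :class:`FluxcompError`, so
callers can catch a single base class at tool boundaries.
"""


class FluxcompError(Exception):
    """Base class for all fluxcomp errors."""


class ValidationError(FluxcompError, ValueError):
    """Input data violates a structural or conservation constraint."""


class DegenerateStateError(FluxcompError, ZeroDivisionError):
    """The response denominator vanished: all target is bound to fully
    saturated competitors, so the steady-state response is undefined."""


class UndefinedRatioError(FluxcompError, ZeroDivisionError):
    """A ratio relation was requested with a zero reference quantity."""


class ConvergenceError(FluxcompError, RuntimeError):
    """A numerical solver failed to reach steady state.

    Carries the last state reached in ``last_state`` when available.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
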