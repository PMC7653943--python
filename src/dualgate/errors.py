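"""Exception hierarchy shared across the package."""


class DualGateError(Exception):
    """Base class for all dualgate errors."""


class InvalidGateCountError(DualGateError, ValueError):
    """A gate count was below 1 or an (r, p) combination is impossible."""


class UnidentifiableParameterError(DualGateError, ValueError):
    """The sample design cannot identify one or more model parameters."""


class FitFailureError(DualGateError, RuntimeError):
    """An iterative fit did not converge.

    Carries the last residual vector in ``residuals`` when available.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class DegenerateFitError(DualGateError, ValueError):
    """A regression input is degenerate (e.g. all abscissae identical)."""


class NoFeasibleSchemeError(DualGateError, ValueError):
    """No cell of a motion grid reaches the requested capture threshold."""


class DomainError(DualGateError, ValueError):
    """An argument lies outside a model's declared domain."""


class InputError(DualGateError, ValueError):
    """Malformed or inconsistent input data (lengths, emptiness, bounds)."""


class EmptySignalError(InputError):
    """A physiological signal contains no valid samples."""


class InsufficientTriggersError(InputError):
    """Fewer than two R-peaks: no cardiac cycle can be formed."""


class LocalisationError(DualGateError, RuntimeError):
    """A hot-spot locator found no usable maximum."""


class ExtractionError(DualGateError, RuntimeError):
    """Myocardium extraction produced an empty mask."""


class ProfileError(DualGateError, ValueError):
    """A line profile is degenerate or has no half-maximum crossing."""


class SnrError(DualGateError, ValueError):
    """SNR is undefined for the given volume of interest."""
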