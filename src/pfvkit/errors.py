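"""Exception and warning types for pfvkit."""


class PfvError(Exception):
    """Base class for all pfvkit errors."""


class FormatError(PfvError):
    """A voltammogram or table file violates the expected dialect."""


class SegmentationError(PfvError):
    """The potential program cannot be split into monotone sweep segments."""


class StiffnessError(PfvError):
    """Numerical integration of the interfacial kinetics produced non-finite
    values; retry with a smaller ``potential_step``."""


class NoPeakError(PfvError):
    """No peak above the noise floor could be located in a sweep segment."""


class ConvergenceError(PfvError):
    """A nonlinear fit failed to converge from every starting point."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class PfvWarning(UserWarning):
    """Base class for pfvkit warnings."""


class BaselineWarning(PfvWarning):
    """Peak interferes with a baseline flank window."""


class LackOfFitWarning(PfvWarning):
    """A linear regression shows systematic lack of fit (runs test)."""


class KineticsWarning(PfvWarning):
    """Rate-constant extraction is degraded (reversible data, method
    disagreement, out-of-range peak separations, ...)."""


class DistanceWarning(PfvWarning):
    """A tunneling-distance estimate fell in an unphysical range."""


class FitBoundaryWarning(PfvWarning):
    """A fitted parameter landed on (or beyond) its allowed bound."""
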