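"""Exception and warning types shared across the package."""


class SeagrassIBLError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(SeagrassIBLError, ValueError):
    """Projection line is (numerically) parallel to the boundary line."""


class ZeroCapacityError(SeagrassIBLError, ZeroDivisionError):
    """A carrying capacity is zero; the logistic scaling is undefined."""


class InsufficientDataError(SeagrassIBLError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateDirectionError(SeagrassIBLError, ValueError):
    """Point cloud has no dominant direction (isotropic covariance)."""


class IndeterminateRateError(SeagrassIBLError, ValueError):
    """All calibration points sit at the carrying capacity (x ~ 1)."""


class SimulationError(SeagrassIBLError, RuntimeError):
    """A trajectory step failed; carries the step index in the message."""


class GrowthDomainWarning(UserWarning):
    """log10 state crossed zero: the logistic term reverses sign there."""


class BoundaryViolationWarning(UserWarning):
    """Generated observations lie implausibly far above the boundary line."""
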