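"""Exception hierarchy shared across the package."""


class StrainCVError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StrainCVError, ValueError):
    """Invalid inputs: bad labels, mismatched field lengths, bad specs."""


class GeometryError(StrainCVError):
    """No real geometry satisfies the requested dimensions."""


class IntegrationError(StrainCVError):
    """The ODE/PDE integration produced non-finite state."""


class MeasurementError(StrainCVError):
    """A trace or record does not contain the feature to be measured."""


class CalibrationError(StrainCVError):
    """Conductivity calibration could not bracket or reach the target CV."""


class FitError(StrainCVError):
    """Degenerate samples made the strain-CV fit impossible."""


class ProtocolError(StrainCVError):
    """A pacing protocol precondition failed (e.g. S1 did not capture)."""


class ProjectionError(StrainCVError):
    """A fine-mesh point lies too far outside the coarse mesh support."""
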