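"""Exception hierarchy for the stereology pipeline."""


class StereologyError(ValueError):
    """Base class for all pipeline errors."""


class InvalidParameterError(StereologyError):
    """A probe or estimator parameter violates its precondition."""


class InvalidGeometryError(StereologyError):
    """Phantom geometry is inconsistent (non-monotone radii, bad scales)."""


class SamplingInfeasibleError(StereologyError):
    """A sampling design cannot be realized (e.g. region too small for frames)."""


class UndefinedEstimateError(StereologyError):
    """An estimator's denominator is zero (no points, no frames, n < 2)."""


class CalibrationError(StereologyError):
    """Phantom calibration targets are infeasible."""


class SchemaError(StereologyError):
    """An input table violates the counts/estimates schema."""
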