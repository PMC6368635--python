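"""Exception hierarchy for sbtsim."""


class SbtsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(SbtsimError):
    """Conduit geometry or gas property is physically invalid (non-positive)."""


class InvalidInputError(SbtsimError):
    """A physical input is outside its valid domain."""


class SimulationDivergedError(SbtsimError):
    """The fixed-step integration left the physically plausible volume range."""

    def __init__(self, message: str, dt: float | None = None):
        super().__init__(message)
        self.dt = dt


class CalibrationError(SbtsimError):
    """Constant-VT effort calibration failed to bracket the target volume."""

    def __init__(self, message: str, achieved_vt_ml: float | None = None):
        super().__init__(message)
        self.achieved_vt_ml = achieved_vt_ml


class WindowUndefinedError(SbtsimError):
    """A per-breath metric window cannot be located in the trace."""


class InsufficientDataError(SbtsimError):
    """Too few sweep conditions for the requested regression."""


class FitFailureError(SbtsimError):
    """Nonlinear least squares failed to converge."""


class NoIntersectionError(SbtsimError):
    """A regression line with zero slope has no intersection with a reference."""


class TableSchemaError(SbtsimError):
    """A delimited-text table does not match the expected column schema."""
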