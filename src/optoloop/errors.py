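"""Exception types shared across the package."""


class OptoloopError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(OptoloopError):
    """Domain or stimulus geometry is degenerate (empty mask, bad diameter...)."""


class ConfigError(OptoloopError):
    """A configuration value is out of range or internally inconsistent."""


class IntegrationDivergedError(OptoloopError):
    """The explicit integrator produced non-finite state.

    Carries the step index at which divergence was first observed.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class MeasurementUndefinedError(OptoloopError):
    """A physiological measurement was requested on insufficient activity."""


class MetadataError(OptoloopError):
    """A movie container is missing required metadata attributes."""
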