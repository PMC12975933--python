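"""Exception hierarchy shared across the package."""


class MABeautyError(Exception):
    """Base class for all package-specific errors."""


class SchemaMismatchError(MABeautyError):
    """A landmark record does not match the declared schema (e.g. wrong point count)."""


class LandmarkParseError(MABeautyError):
    """A landmark file could not be parsed; carries the offending line where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegeneracyError(MABeautyError):
    """Geometric input is degenerate (coincident points, zero heights, ...)."""


class InsufficientPointsError(MABeautyError):
    """Too few points for the requested geometric fit."""


class ConfigError(MABeautyError):
    """An invalid configuration value."""


class NotFittedError(MABeautyError):
    """A model was used before training."""
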