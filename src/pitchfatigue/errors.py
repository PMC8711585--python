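"""Exception hierarchy for the pitchfatigue package."""


class PitchFatigueError(Exception):
    """Base class for all package-specific errors."""


class PoseParseError(PitchFatigueError):
    """A keypoint file could not be parsed."""


class EmptyFrameError(PitchFatigueError):
    """A keypoint file contains no detected people."""


class DegenerateGeometryError(PitchFatigueError):
    """An angle was requested between zero-length vectors."""


class MissingFrameError(PitchFatigueError):
    """A pitch event has no matching pose frame."""


class SchemaError(PitchFatigueError):
    """A tabular input violates its declared schema."""


class ParameterError(PitchFatigueError):
    """A parameter is outside its valid range."""


class InsufficientDataError(PitchFatigueError):
    """An interval has too few present values to estimate statistics."""


class DegenerateBoundsError(PitchFatigueError):
    """Feature bounds have zero or wrong-signed ramp width."""


class NoDetectionError(PitchFatigueError):
    """No training game produced a fatigue point."""


class ConstructionError(PitchFatigueError):
    """A synthetic frame cannot realize the requested angles."""
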