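"""Exception hierarchy for the beltspeed package."""


class BeltspeedError(Exception):
    """Base class for all package-specific errors."""


class C3DFormatError(BeltspeedError):
    """The .c3d file is unreadable or violates the expected layout."""


class EmptyCaptureError(BeltspeedError):
    """The capture contains no frames or no usable trajectories."""


class ConfigError(BeltspeedError):
    """A configuration value violates its invariants."""


class DegenerateGeometryError(BeltspeedError):
    """Marker geometry is degenerate (e.g. coincident alignment markers)."""


class EmptyResultError(BeltspeedError):
    """A pipeline stage eliminated every remaining trajectory.

    ``stage`` names the stage that removed the last candidate.
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no belt markers survived stage '{stage}'")


class GapTooLongError(BeltspeedError):
    """A run of frames with no surviving markers exceeds the allowed span."""


class SeriesTooShortError(BeltspeedError):
    """The series is too short for stable zero-phase filtering."""


class InsufficientDataError(BeltspeedError):
    """Too few gait cycles were detected to analyze the trial."""


class EventPairingError(BeltspeedError):
    """Touchdown/toe-off candidates could not be paired consistently."""


class EventClassificationError(BeltspeedError):
    """Knee-extension peaks could not be classified into touchdown/toe-off."""

    def __init__(self, frame: int, message: str | None = None):
        self.frame = frame
        super().__init__(message or f"unclassifiable extension peak at frame {frame}")
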