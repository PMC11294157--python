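"""Exception and warning types shared across the package."""


class TrunkTrackError(Exception):
    """Base class for all trunktrack errors."""


class DegenerateGeometry(TrunkTrackError):
    """Marker geometry cannot define a frame (zero/parallel/collinear vectors)."""


class MissingMarker(TrunkTrackError):
    """A required marker label is absent from the trial."""

    def __init__(self, marker: str, context: str = ""):
        self.marker = marker
        msg = f"required marker {marker!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class EmptyTrial(TrunkTrackError):
    """No usable (unoccluded) frames in a trial."""


class TooShortSeries(TrunkTrackError):
    """Series too short for the requested operation."""


class NonUniformSampling(TrunkTrackError):
    """Sample times are not uniformly spaced."""


class EventsNotFound(TrunkTrackError):
    """Required movement-cycle events could not be detected."""


class EmptyCycle(TrunkTrackError):
    """No valid samples inside the requested movement cycle."""


class LengthMismatch(TrunkTrackError):
    """Paired samples have different lengths."""


class SampleTooSmall(TrunkTrackError):
    """Sample size outside the valid range for a statistic."""


class DegenerateVariance(TrunkTrackError):
    """A variance required by a statistic is zero."""


class MissingReference(TrunkTrackError):
    """Reference (Definition Model) values absent from a metric table."""


class FormatError(TrunkTrackError):
    """Malformed trajectory file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownUnits(FormatError):
    """Unrecognised units declaration in a trajectory file."""


class ConfigError(TrunkTrackError):
    """Invalid run or generator configuration."""


# ---------------------------------------------------------------------------
# warnings

class AllZeroDifferences(UserWarning):
    """Every paired difference is zero; the signed-rank test is vacuous."""


class SingleSexCohort(UserWarning):
    """Only one sex label present; between-sex differences are omitted."""


class GimbalWarning(UserWarning):
    """Obliquity within tolerance of +/-90 deg; tilt/axial split is ill-conditioned."""


class GapWarning(UserWarning):
    """Occlusion gap too long to interpolate; frames remain missing."""
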