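"""Exception hierarchy shared across the pipeline.

All validation failures derive from :class:`OccireachError` so the CLI can
map them onto exit code 1 (validation) versus 2 (unexpected runtime error).
"""


class OccireachError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(OccireachError, ValueError):
    """An argument violates a documented precondition."""


class MissingMarkerError(OccireachError, KeyError):
    """A required marker is absent from a recording."""

    def __init__(self, marker: str, trial_id: str | None = None):
        self.marker = marker
        self.trial_id = trial_id
        where = f" in trial {trial_id!r}" if trial_id else ""
        super().__init__(f"required marker {marker!r} missing{where}")


class DegenerateFrameError(OccireachError):
    """Markers collinear/coincident in a frame; segment basis undefined."""

    def __init__(self, frame: int, detail: str = ""):
        self.frame = frame
        super().__init__(f"degenerate marker configuration at frame {frame}: {detail}")


class NoMotionDetectedError(OccireachError):
    """No onset/end run satisfying the speed-threshold rule was found."""


class RateMismatchError(OccireachError):
    """Trials in one batch were recorded at different sampling rates."""


class TrialParseError(OccireachError):
    """A TRC or CSV trial file could not be parsed."""

    def __init__(self, path, line: int | None, detail: str):
        self.path = path
        self.line = line
        at = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{at}: {detail}")


class UndefinedStatisticError(OccireachError):
    """A statistic is undefined for the given sample (e.g. constant input)."""


class RankDeficiencyError(OccireachError):
    """Design or covariance matrix is singular."""


class DegenerateForestError(OccireachError):
    """Feature table cannot support an unsupervised forest (constant columns)."""


class NoSolutionError(OccireachError):
    """A search (e.g. sample-size) has no attainable solution."""
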