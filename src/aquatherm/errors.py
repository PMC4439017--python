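"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`AquathermError` so that the
orchestrator can attach stage names while preserving the original type.
"""


class AquathermError(Exception):
    """Base class for all aquatherm errors."""


class FormatError(AquathermError):
    """Input file does not match the documented column layout."""


class EmptyInputError(AquathermError):
    """Input file or record collection is empty."""


class DuplicateRecordError(AquathermError):
    """Duplicate (tank, depth, timestamp) or similar key collision."""


class GapError(AquathermError):
    """More consecutive missing logger readings than the fill policy allows."""


class OutOfRangeError(AquathermError):
    """Depth or time requested outside the span of a temperature profile."""


class GridMismatchError(AquathermError):
    """Profiles compared on non-identical depth/time grids."""


class ParameterError(AquathermError):
    """An argument outside its documented domain (threshold, convention...)."""


class SampleSizeError(AquathermError):
    """Too few observations for the requested estimate."""


class DesignError(AquathermError):
    """Degenerate statistical design (empty cell, single group, ...)."""


class LabelError(AquathermError):
    """Unknown species or group label."""


class MissingDataError(AquathermError):
    """A required field (e.g. assigned body temperature) is absent."""


class JoinError(AquathermError):
    """Observations reference tanks or species with no matching profile/range."""


class ConfigError(AquathermError):
    """Invalid simulation or run configuration."""


class StageError(AquathermError):
    """Pipeline stage failure wrapping the underlying error.

    Attributes
    ----------
    stage : str
        Name of the pipeline stage that failed.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
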