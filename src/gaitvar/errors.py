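"""Exception hierarchy for the gaitvar pipeline.

Every error raised by the library derives from :class:`GaitVarError` so
callers can catch pipeline failures without masking programming errors.
"""


class GaitVarError(Exception):
    """Base class for all gaitvar errors."""


class ConfigError(GaitVarError, ValueError):
    """A simulation or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class KeypointSchemaError(GaitVarError, ValueError):
    """A keypoint JSON file does not conform to the trial schema."""


class InsufficientFramesError(GaitVarError, ValueError):
    """Fewer than two usable frames survive; displacements are undefined."""


class InsufficientDataError(GaitVarError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(GaitVarError, ValueError):
    """A variable has zero variance where spread is required."""


class IncompleteTrialsError(GaitVarError, ValueError):
    """A subject is missing one of the per-foot/per-trial variances."""


class PipelineStageError(GaitVarError, RuntimeError):
    """Wraps any stage failure with the stage name and subject context."""
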