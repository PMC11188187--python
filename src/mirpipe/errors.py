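"""Exception hierarchy.

Every error raised by the package derives from :class:`MirpipeError` so that
callers (and the CLI) can distinguish pipeline failures from programming bugs.
"""


class MirpipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirpipeError):
    """An invalid generator or run configuration; names the offending field."""


class QCError(MirpipeError):
    """Raw-array quality control cannot proceed (e.g. <2 BLANK spots)."""


class AssemblyError(MirpipeError):
    """Per-sample columns cannot be assembled into one matrix."""


class ImputationError(MirpipeError):
    """An imputer's precondition is violated."""


class NormalizationError(MirpipeError):
    """A normalization precondition is violated (zero median, entry <= 0 ...)."""


class BatchCorrectionError(MirpipeError):
    """Batch correction precondition violated (missing entries, tiny batch)."""


class PipelineError(MirpipeError):
    """A stage failed during pipeline execution; carries pipeline context."""

    def __init__(self, message, pipeline_id=None, stage_index=None):
        super().__init__(message)
        self.pipeline_id = pipeline_id
        self.stage_index = stage_index


class EvaluationError(MirpipeError):
    """Agreement / batch-effect evaluation cannot be computed."""


class RawParseError(MirpipeError):
    """A raw-array or matrix file is malformed; names the line when known."""


class SchemaError(RawParseError):
    """A file violates the closed column/vocabulary schema."""
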