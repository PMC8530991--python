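"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ReciprotraceError` so the
orchestrator can attribute failures to a stage and input file.
"""


class ReciprotraceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ReciprotraceError):
    """Invalid generator or run configuration."""


class SchemaError(ReciprotraceError):
    """Input table is missing required columns or group labels."""


class ValidationError(ReciprotraceError):
    """Input values violate a contract (duplicates, negatives, bad labels)."""


class NormalizationError(ReciprotraceError):
    """Size-factor computation cannot proceed."""


class ComputationError(ReciprotraceError):
    """A downstream computation received degenerate input (e.g. empty universe)."""


class PipelineError(ReciprotraceError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"stage '{stage}': {detail}")
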