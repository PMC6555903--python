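"""Exception hierarchy for probe-table handling and analysis stages."""


class MWTrajError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MWTrajError):
    """Probe-table header or enum label does not match the documented dialect."""


class TimestampParseError(MWTrajError):
    """A timestamp field could not be parsed as ISO-8601."""


class NotReportRangeError(MWTrajError):
    """A number-of-thoughts report lies outside the 0..10 dropdown range."""


class ValidationError(MWTrajError):
    """A probe table violates a structural invariant (ordering, duplicates, windows)."""


class NoAnalyzableDataError(MWTrajError):
    """Exclusion rules removed every usable probe."""


class ParameterError(MWTrajError):
    """Simulation or analysis parameters are infeasible or out of range."""


class DegenerateDataError(MWTrajError):
    """A statistical test received data it cannot be computed on."""


class EmptySegmentsError(MWTrajError):
    """No mind-wandering probes available to anchor event-locked segments."""


class PipelineError(MWTrajError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
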