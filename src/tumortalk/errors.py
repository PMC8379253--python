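"""Exception hierarchy for tumortalk."""


class TumortalkError(Exception):
    """Base class for all package errors."""


class ConfigError(TumortalkError):
    """Invalid simulation or pipeline configuration."""


class QCEmptyError(TumortalkError):
    """Quality-control filtering removed every cell.

    Carries per-criterion removal tallies so the caller can see which
    threshold was responsible.
    """

    def __init__(self, tallies: dict):
        self.tallies = dict(tallies)
        super().__init__(
            "QC filtering removed all cells; removed per criterion: "
            + ", ".join(f"{k}={v}" for k, v in self.tallies.items())
        )


class PipelineError(TumortalkError):
    """A pipeline stage failed; names the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
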