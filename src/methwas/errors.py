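"""Exception hierarchy for the methwas pipeline."""


class MethwasError(Exception):
    """Base class for all methwas-specific errors."""


class ConfigurationError(MethwasError, ValueError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class MatrixFormatError(MethwasError, ValueError):
    """A malformed probe x sample matrix file."""


class EmptyCohortError(MethwasError, ValueError):
    """All probes or all samples were removed by quality control."""


class IslandNameError(MethwasError, ValueError):
    """A CpG-island name string that does not follow the chrN_CLASS:start-end grammar."""

    def __init__(self, name: str, message: str = ""):
        self.name = name
        detail = f": {message}" if message else ""
        super().__init__(f"malformed island name {name!r}{detail}")


class DesignMatrixError(MethwasError, ValueError):
    """A rank-deficient or otherwise unusable design matrix."""


class PipelineStageError(MethwasError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
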