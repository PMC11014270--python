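"""Exception and warning types shared across the toolkit."""


class NirquantError(Exception):
    """Base class for all toolkit errors."""


class DomainError(NirquantError, ValueError):
    """An argument is outside the mathematically admissible domain."""


class ConfigurationError(NirquantError, ValueError):
    """An instrument tag, architecture tag or config block is not recognized."""


class SpectralFormatError(NirquantError, ValueError):
    """A spectral file violates the on-disk contract (ragged row, bad value,
    axis/sidecar mismatch). The message names the offending row/column."""


class DegenerateInputError(NirquantError, ValueError):
    """Input with no usable variation (constant spectrum, all-equal weights)."""


class DimensionError(NirquantError, ValueError):
    """Array shape incompatible with the fitted model or operation."""


class TrainingDivergedError(NirquantError, RuntimeError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training loss became non-finite at epoch {epoch}")


class PipelineStageError(NirquantError, RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, cause: BaseException, manifest=None):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


class PrecisionWarning(UserWarning):
    """Finite-difference step too small for the model's numeric resolution."""
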