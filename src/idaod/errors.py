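"""Exception hierarchy for the idaod pipeline.

Validation problems (bad configs, bad input values) derive from
:class:`ValidationError`; runtime problems (divergent training, I/O failures
mid-run) derive from :class:`PipelineRuntimeError`. The CLI maps these onto
exit codes 2 and 3 respectively.
"""


class IdaodError(Exception):
    """Base class for all idaod-specific errors."""


class ValidationError(IdaodError):
    """Invalid inputs, configuration values, or domain violations."""


class PipelineRuntimeError(IdaodError):
    """Failures occurring while a pipeline stage is executing."""


class FastaParseError(ValidationError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class EmptyInputError(ValidationError):
    """No usable records after parsing and validation."""


class SequenceValidationError(ValidationError):
    """A sequence contains letters outside the 20-residue alphabet."""


class ShortSequenceError(ValidationError):
    """A sequence is too short for the requested gap value."""


class ConfigError(ValidationError):
    """A configuration file or object failed validation."""


class StratificationError(ValidationError):
    """A class has too few members to fill every cross-validation fold."""


class FeasibilityError(ValidationError):
    """t-SNE settings are infeasible for the given number of points."""


class DegenerateTrainingError(ValidationError):
    """Supervised training was asked to fit a single-class dataset."""


class DivergenceError(PipelineRuntimeError):
    """Training produced a non-finite loss; carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        self.epoch = epoch
        if epoch is not None:
            message = f"{message} (epoch {epoch})"
        super().__init__(message)
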