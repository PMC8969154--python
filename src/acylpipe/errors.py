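"""Exception and warning hierarchy shared across the pipeline."""


class AcylPipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(AcylPipeError, ValueError):
    """A configuration value violates a precondition."""


class EmptyCohortError(AcylPipeError):
    """A sample filter removed every sample."""


class InsufficientDataError(AcylPipeError):
    """Not enough observations to compute the requested statistic."""


class UnknownGeneError(AcylPipeError, KeyError):
    """A queried gene id is absent from the matrix."""


class NormalizationError(AcylPipeError):
    """Protein-level normalization is impossible for a sample."""


class UnimputableSampleError(AcylPipeError):
    """A sample has no observed intensities to resample from."""


class CoordinateError(AcylPipeError, ValueError):
    """A residue-coordinate mapping produced a non-positive position."""


class AssayDirectionError(AcylPipeError):
    """Absorbance increases where the assay requires a decay."""


class DegenerateNullWarning(UserWarning):
    """The resampled null has zero spread; thresholds are degenerate."""


class ZeroVarianceWarning(UserWarning):
    """Zero-variance genes were dropped before correlation."""


class TruncatedResultWarning(UserWarning):
    """A requested result size exceeded what the data can supply."""
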