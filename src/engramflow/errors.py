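"""Exception types shared across the pipeline stages."""


class EngramflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EngramflowError):
    """A cohort/effect/run configuration violates its invariants."""


class InputError(EngramflowError):
    """Malformed input data (bad symbols, missing columns, ...)."""


class DegenerateVoxelError(EngramflowError):
    """MRS voxel is (nearly) pure CSF; tissue correction is undefined."""


class EmptyRoiError(EngramflowError):
    """ROI definition produced no voxels (e.g. an empty conjunction)."""


class DegenerateDataError(EngramflowError):
    """Data are degenerate for the requested statistic (constant input,
    insufficient n, non-positive-definite correlation triplet, ...)."""


class UndefinedGainError(EngramflowError):
    """Overnight gain is undefined (zero day-1 reference performance)."""
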