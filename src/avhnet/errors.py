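"""Exception hierarchy shared across the pipeline stages."""


class AvhnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AvhnetError, ValueError):
    """A file does not match the documented on-disk layout."""


class DimensionError(AvhnetError, ValueError):
    """A matrix dimension does not match the node table."""


class PairingError(AvhnetError, ValueError):
    """Baseline/post rows cannot be paired by subject_id."""


class InsufficientDataError(AvhnetError, ValueError):
    """Too few observations for the requested computation."""


class DegenerateSparsityError(AvhnetError, ValueError):
    """A sparsity level retains zero edges."""


class UndefinedMetricError(AvhnetError, ValueError):
    """A graph metric is undefined for this input (e.g. edgeless graph)."""


class DegenerateNullError(AvhnetError, ValueError):
    """A null-model reference mean is zero."""


class CollinearityError(AvhnetError, ValueError):
    """The covariate design matrix is rank deficient."""


class DegenerateVarianceError(AvhnetError, ValueError):
    """A test statistic is undefined because a variance is zero."""


class ParameterError(AvhnetError, ValueError):
    """A cohort-spec or config parameterization is invalid."""


class ConfigError(AvhnetError, ValueError):
    """A run configuration fails validation."""
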