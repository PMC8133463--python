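"""Exception hierarchy for the climate-envelope pipeline."""


class ClimenvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClimenvError, ValueError):
    """Invalid or inconsistent configuration values."""


class SchemaError(ClimenvError, ValueError):
    """Inputs do not match the expected bands/columns/geometry."""


class EmptyTableError(ClimenvError, ValueError):
    """No usable rows remain after filtering."""


class UnsampleableError(ClimenvError, ValueError):
    """A sampling surface has no support."""


class InfeasibleSamplingError(ClimenvError, RuntimeError):
    """Rejection sampling exhausted its proposal budget."""


class DegenerateFitError(ClimenvError, ValueError):
    """The training data cannot identify a model (e.g. single-class response)."""


class DegenerateFoldError(DegenerateFitError):
    """A cross-validation fold has a single-class training set."""


class UndefinedMetricError(ClimenvError, ValueError):
    """A metric (AUC, kappa, percentage) is undefined for the given inputs."""
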