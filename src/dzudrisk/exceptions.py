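"""Exception hierarchy for the dzudrisk package."""


class DzudRiskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DzudRiskError, ValueError):
    """An invalid simulation or analysis configuration value; names the field."""


class DataValidationError(DzudRiskError, ValueError):
    """An input table violates its schema or an invariant (names record)."""


class PanelError(DzudRiskError, ValueError):
    """A risk panel cannot be built or is unusable for modelling."""


class FitError(DzudRiskError, RuntimeError):
    """Model fitting failed (rank deficiency, divergence, degenerate data)."""


class CrossValidationError(DzudRiskError, RuntimeError):
    """Leave-one-out cross-validation could not produce a Q² statistic."""


class SelectionError(DzudRiskError, ValueError):
    """Indicator screening/selection failed (e.g. a group with no usable r)."""
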