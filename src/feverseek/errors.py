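"""Exception hierarchy for the feverseek pipeline."""


class FeverseekError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FeverseekError):
    """An invalid configuration value, naming the offending field."""


class BoundsError(FeverseekError):
    """A requested country/year lies outside the available data."""


class DegenerateDenominatorError(FeverseekError):
    """Empty input or all-zero weights in a weighted proportion."""


class DegenerateScaleError(FeverseekError):
    """A covariate is constant and cannot be standardised."""


class RankError(FeverseekError):
    """More principal components requested than the matrix rank supports."""


class BasisError(FeverseekError):
    """Too few distinct inputs to build a spline basis."""


class IdentifiabilityError(FeverseekError):
    """The model design is singular after constraints."""


class ConvergenceError(FeverseekError):
    """The smoothing-parameter search failed to converge."""


class MissingEffectError(FeverseekError):
    """Prediction requested for a country with no fitted or donor effect."""


class AlignmentError(FeverseekError):
    """Realisation cubes do not share dimensions or alignment."""


class WeightingError(FeverseekError):
    """Zero total population in a population-weighted aggregate."""


class EnsembleError(FeverseekError):
    """Too many ensemble runs failed."""


class SummaryError(FeverseekError):
    """An empty realisation cube cannot be summarised."""
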