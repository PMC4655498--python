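"""Exception hierarchy for the model pipeline."""


class PPHEconError(Exception):
    """Base class for all package-specific errors."""


class EvidenceIncompleteError(PPHEconError, LookupError):
    """A requested baseline rate or relative risk is absent from the evidence set."""


class UndefinedEffectError(PPHEconError, ValueError):
    """A pooled effect cannot be estimated (e.g. zero events in every trial arm)."""


class InvalidParameterError(PPHEconError, ValueError):
    """A numeric model input is outside its valid domain."""


class IncomparableResultsError(PPHEconError, ValueError):
    """Two cohort results were computed under different cohort sizes or setting mixes."""


class InvalidRecipeError(PPHEconError, ValueError):
    """A treatment-recipe parameter is outside its valid domain."""


class ProbabilityOverflowError(PPHEconError, ValueError):
    """A baseline rate times a relative risk exceeds 1, so no Bernoulli draw exists."""


class UnsupportedSubstitutionError(PPHEconError, ValueError):
    """A one-way sensitivity substitution names an unknown target parameter."""


class ConfigError(PPHEconError, ValueError):
    """A configuration file failed schema validation; the message names the key."""
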