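"""Exception hierarchy shared across the package."""


class LincSyntenyError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(LincSyntenyError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidInputError(LincSyntenyError, ValueError):
    """An operation received input outside its documented domain."""


class DataError(LincSyntenyError, ValueError):
    """Input tables are internally inconsistent (e.g. a non-1-to-1 ortholog map)."""


class LookupError_(LincSyntenyError, KeyError):
    """An identifier was not found where the contract requires it."""


class NormalizationError(LincSyntenyError, ValueError):
    """Size-factor normalization is impossible (no gene positive in all samples)."""


class InvalidContrastError(LincSyntenyError, ValueError):
    """A differential-expression contrast references a missing zone."""


class ModelAssumptionError(LincSyntenyError, ValueError):
    """A model precondition (e.g. ultrametricity) does not hold."""


class CalibrationMissingError(LincSyntenyError, ValueError):
    """No E-value calibration is available for the requested scoring scheme."""


class UndefinedStatisticError(LincSyntenyError, ValueError):
    """A statistic is undefined for the given input (e.g. expected count <= 0)."""
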