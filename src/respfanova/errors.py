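"""Exception types shared across the pipeline."""


class RespfanovaError(Exception):
    """Base class for all package errors."""


class ConfigError(RespfanovaError, ValueError):
    """Invalid simulation or run configuration."""


class FormatError(RespfanovaError, ValueError):
    """Malformed input file (missing columns, bad labels)."""


class CompletenessError(RespfanovaError, ValueError):
    """Crossover completeness violated: a subject lacks one condition."""


class CoverageError(RespfanovaError, ValueError):
    """Requested grid points fall outside the observed time range."""


class DomainError(RespfanovaError, ValueError):
    """Value outside the mathematical domain of a transform (e.g. log of <= 0)."""


class DegenerateInputError(RespfanovaError, ValueError):
    """Statistic undefined on the given input (e.g. zero-variance differences)."""


class NumericalError(RespfanovaError, ArithmeticError):
    """Non-finite or singular intermediate quantity."""
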