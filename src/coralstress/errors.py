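"""Exception hierarchy for the coralstress pipeline."""


class CoralStressError(Exception):
    """Base class for all coralstress errors."""


class InvalidArgumentError(CoralStressError, ValueError):
    """An argument violates a documented precondition."""


class NonAmplifyingSeriesError(CoralStressError):
    """Dilution series whose CP does not decrease with template amount.

    A valid qPCR standard curve must have a negative slope of CP on
    log2(input): more template crosses the detection threshold earlier.
    """


class InsufficientDataError(CoralStressError):
    """Too few samples/observations to compute the requested quantity."""


class DegenerateDesignError(CoralStressError):
    """Experimental design cannot identify the requested effect."""


class ConfigurationError(CoralStressError):
    """Inconsistent or incomplete run configuration."""


class SchemaError(CoralStressError):
    """Input table does not match the documented column contract."""


class FittingError(CoralStressError):
    """Model fitting failed in a way the caller must handle."""
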