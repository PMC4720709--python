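"""Package-specific exception types."""


class SDEBayesError(Exception):
    """Base class for all sdebayes errors."""


class InvalidSpecError(SDEBayesError):
    """An SDE specification is malformed or non-evaluable."""


class InvalidInputError(SDEBayesError):
    """An input array or file does not satisfy a documented contract."""


class InsufficientDataError(SDEBayesError):
    """Too few sample paths for the requested statistic."""


class NumericalError(SDEBayesError):
    """A numerical step failed (singular factor, non-finite value, ...)."""


class ImproperPriorError(SDEBayesError):
    """Hyperparameters violate the propriety/moment-existence conditions."""
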