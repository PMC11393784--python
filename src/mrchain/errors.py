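"""Exception hierarchy shared across the package."""


class MRChainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRChainError):
    """A user-supplied configuration value or file layout is invalid."""


class EmptyInputError(MRChainError):
    """An operation received (or produced) zero usable variants."""


class InsufficientInstrumentsError(MRChainError):
    """Fewer instruments than the estimator's minimum requirement."""


class UndefinedProportionError(MRChainError):
    """Mediated proportion is undefined because the total effect is zero."""
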