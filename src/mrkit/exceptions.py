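"""Exception hierarchy for mrkit."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """A column map, selection config, or run config is invalid."""


class InputError(MRKitError):
    """An input file is missing, empty, or structurally unreadable."""


class DomainError(MRKitError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class EstimationError(MRKitError):
    """Too few instruments, or a degenerate configuration, for an estimator."""


class CollinearityError(EstimationError):
    """The multivariable design matrix is rank deficient."""

    def __init__(self, message, exposures=None):
        super().__init__(message)
        self.exposures = list(exposures or [])
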