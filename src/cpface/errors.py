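"""Exception hierarchy shared across the package."""


class CpfaceError(Exception):
    """Base class for all package errors."""


class DomainError(CpfaceError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(CpfaceError, ValueError):
    """An invalid configuration object or unknown experiment id."""


class SimulationError(CpfaceError, RuntimeError):
    """A stochastic simulation failed to produce a valid draw."""


class UnattainableCriterionError(DomainError):
    """A percent-correct criterion outside the feasible (guess, 1-lapse) range."""


class ContractError(CpfaceError, ValueError):
    """A cross-operation contract violation (non-nested models, mismatched data)."""


class MalformedDataError(CpfaceError, ValueError):
    """More than the tolerated fraction of input rows failed schema validation."""
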