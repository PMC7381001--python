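"""Exception hierarchy shared across the package."""


class CycleStatsError(Exception):
    """Base class for all package errors."""


class FormatError(CycleStatsError):
    """An input file does not conform to the documented dialect."""


class ReferentialError(CycleStatsError):
    """An event refers to an unknown user or violates a date invariant."""


class ConfigError(CycleStatsError):
    """Invalid configuration or parameter set."""


class ContractError(CycleStatsError):
    """A function precondition was violated by the caller."""


class InsufficientDataError(CycleStatsError):
    """Too few observations to compute the requested statistic."""
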