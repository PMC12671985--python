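"""Exception hierarchy for the pmcal pipeline."""


class PmcalError(Exception):
    """Base class for all pmcal errors."""


class FormatError(PmcalError):
    """An input file does not match the expected CSV dialect."""


class EmptyInputError(PmcalError):
    """An input file contained no usable rows."""


class ConfigError(PmcalError):
    """A configuration value violates its constraints."""


class ContractError(PmcalError):
    """An operation was called outside its preconditions."""


class DependencyError(PmcalError):
    """A pipeline stage is missing an upstream artifact."""
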