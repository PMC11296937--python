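"""Exception hierarchy: configuration vs row-level validation vs structure."""


class SpliceformError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpliceformError):
    """Fatal problem with inputs as configured (missing column, bad path)."""


class ValidationError(SpliceformError):
    """Row- or record-level problem in otherwise well-formed input."""


class StructuralError(SpliceformError):
    """Event coordinates inconsistent with the gene model they reference."""


class ContractError(SpliceformError):
    """A precondition of an operation was violated by the caller."""


class UndefinedStatistic(SpliceformError):
    """A statistic is undefined for the given input (e.g. zero spread)."""
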