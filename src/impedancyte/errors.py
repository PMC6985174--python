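"""Exception types shared across the package."""


class ImpedancyteError(Exception):
    """Base class for all package errors."""


class ParameterError(ImpedancyteError, ValueError):
    """A physical or configuration parameter is invalid (non-positive, non-finite...)."""


class DomainError(ImpedancyteError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ProcessingError(ImpedancyteError, RuntimeError):
    """A signal-processing step encountered data it cannot handle."""


class SchemaError(ImpedancyteError, ValueError):
    """A file or table does not match the expected schema."""
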