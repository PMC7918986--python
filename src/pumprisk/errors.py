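"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: schema/config problems exit 2,
data-content problems exit 3.
"""


class PumpRiskError(Exception):
    """Base class for all package errors."""


class SchemaError(PumpRiskError):
    """An input file or config does not match the documented schema."""


class DataError(PumpRiskError):
    """Input values are physically or logically inconsistent."""


class DomainError(PumpRiskError, ValueError):
    """A value is outside the mathematical domain of an operation."""
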