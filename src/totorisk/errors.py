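"""Exception hierarchy shared across the pipeline."""


class TotoriskError(Exception):
    """Base class for all domain errors raised by this package."""


class SchemaError(TotoriskError, ValueError):
    """A tabular input does not conform to the expected schema."""


class DomainError(TotoriskError, ValueError):
    """A numeric argument is outside the mathematically valid domain."""


class UnsupportedElementError(TotoriskError, ValueError):
    """The requested element lacks the constant (RfD or RDI) the operation needs."""


class UndefinedInputError(TotoriskError, ValueError):
    """The operation is undefined for the given (typically empty) input."""
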