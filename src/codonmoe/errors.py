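"""Exception hierarchy shared across the package."""


class CodonMoEError(Exception):
    """Base class for package errors."""


class ParseError(CodonMoEError):
    """A file could not be parsed (malformed record, empty sequence, ...)."""


class ValidationError(CodonMoEError):
    """Input violated a domain invariant (alphabet, duplicate ids, bad target)."""


class SchemaError(CodonMoEError):
    """A table or config is missing required columns/keys or has unknown ones."""


class ContractError(CodonMoEError):
    """An internal call contract was violated (shape/length mismatch)."""


class SequenceLengthError(CodonMoEError):
    """Sequence too short for codon grouping, or longer than a backbone allows."""


class TrainingDivergedError(CodonMoEError):
    """Optimization produced a non-finite loss."""


class InfeasibleBudgetError(CodonMoEError):
    """No hidden width reaches the requested parameter budget within tolerance."""

    def __init__(self, message: str, nearest_count: int | None = None):
        super().__init__(message)
        self.nearest_count = nearest_count
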