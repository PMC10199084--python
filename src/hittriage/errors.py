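"""Exception hierarchy shared across the triage pipeline."""


class HitTriageError(Exception):
    """Base class for all package errors."""


class SchemaError(HitTriageError):
    """A required column or field is missing from an input table."""


class RowParseError(HitTriageError):
    """A cell in a data row could not be parsed; carries the row index."""

    def __init__(self, message: str, row_index: int):
        super().__init__(f"{message} (row {row_index})")
        self.row_index = row_index


class FormatError(HitTriageError):
    """A text input (docking log, XVG, XYZ) does not match its declared layout."""


class AmbiguityError(HitTriageError):
    """Multiple result blocks without ligand identifiers."""


class ContractError(HitTriageError):
    """An operation precondition was violated."""


class ConfigurationError(HitTriageError):
    """A rule/range specification could not be interpreted."""


class FixtureLookupError(HitTriageError, KeyError):
    """Unknown fixture name."""
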