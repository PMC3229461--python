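"""Exception hierarchy shared across the package."""


class SblinkError(Exception):
    """Base class for all package errors."""


class ParseError(SblinkError):
    """Malformed input document (XML syntax, TSV structure...)."""


class UnsupportedLevelError(SblinkError):
    """SBML document declares a level other than 2."""


class IntegrityError(SblinkError):
    """Referential-integrity or uniqueness violation."""


class MalformedUrnError(SblinkError):
    """String is not a well-formed MIRIAM URN."""


class CycleError(SblinkError):
    """Graph offered as a DAG contains a cycle."""

    def __init__(self, message: str, cycle: list | None = None):
        super().__init__(message)
        self.cycle = cycle or []


class LookupFailure(SblinkError, KeyError):
    """Unknown node / model / pathway identifier."""


class ValidationError(SblinkError):
    """Invalid configuration or forbidden construct."""


class BusyError(SblinkError):
    """Concurrent write conflict; the operation may be retried."""
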