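"""Exception hierarchy shared across the toolkit."""


class GitkitError(Exception):
    """Base class for all toolkit errors."""


class MalformedRowError(GitkitError):
    """A tabular input row violates the format (wrong column count, bad number)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class RecordValidationError(GitkitError):
    """A record violates its invariants at write time."""


class StructureError(GitkitError):
    """A taxonomy dump is structurally broken (orphan parent, cycle, no root)."""


class UnknownTaxonError(GitkitError, KeyError):
    """A taxon id was requested that is not in the tree."""


class ArgumentError(GitkitError, ValueError):
    """An operation was called with inconsistent arguments."""
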