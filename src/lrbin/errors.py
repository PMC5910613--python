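"""Exception hierarchy shared across the package.

All errors raised by lrbin derive from :class:`LrbinError` so that callers
(and the CLI) can distinguish bad input from genuine bugs.
"""


class LrbinError(Exception):
    """Base class for all lrbin errors."""


class MalformedTaxonomyError(LrbinError):
    """The taxonomy source violates a structural invariant (cycle, dangling
    parent, duplicate id, missing/multiple roots)."""


class TaxonNotFoundError(LrbinError, KeyError):
    """A taxon id was looked up that does not exist in the tree."""

    def __init__(self, taxon_id):
        super().__init__(taxon_id)
        self.taxon_id = taxon_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown taxon id: {self.taxon_id}"


class AlignmentParseError(LrbinError):
    """An alignment file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConsistencyError(LrbinError):
    """Records that must agree (e.g. read lengths for one read id) do not."""


class ConfigurationError(LrbinError):
    """A parameter combination or requested option is invalid."""


class EvaluationError(LrbinError):
    """Assignment evaluation was asked about a read missing from the truth."""
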