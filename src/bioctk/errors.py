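"""Exception hierarchy for the toolkit.

Data errors derive from :class:`BioCError` so callers (and the CLI) can
distinguish bad input (exit code 1) from bad usage (exit code 2).
"""


class BioCError(Exception):
    """Base class for all data-level errors raised by the toolkit."""


class BioCRangeError(BioCError):
    """A location does not lie within the reconstructable document text."""


class BioCParseError(BioCError):
    """The XML source is not well formed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class BioCFormatError(BioCError):
    """Well-formed XML (or a decodable element) violating the BioC layout."""


class BioCValidationError(BioCError):
    """A collection failed validation; carries the violation records."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.path}: {v.message}" for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"collection failed validation: {lines}{more}")


class PubTatorFormatError(BioCError):
    """A PubTator stream violates the pipe/tab line format."""


class ConversionError(BioCError):
    """A BioC collection cannot be converted (e.g. missing ConceptID infon)."""


class ComparisonError(BioCError):
    """Two collections are not comparable (mismatched document ids)."""


class ContractError(BioCError):
    """A pluggable component (tagger, parser) broke its interface contract."""


class PipelineUsageError(Exception):
    """Unsatisfiable stage selection; a usage error, not a data error."""
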