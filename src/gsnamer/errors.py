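"""Exception hierarchy shared across the package."""


class GsnamerError(Exception):
    """Base class for all package-specific errors."""


class OboParseError(GsnamerError):
    """Malformed OBO document; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class OntologyStructureError(GsnamerError):
    """The ontology graph violates a structural requirement (e.g. a cycle)."""


class UnknownTermError(GsnamerError, KeyError):
    """A term id was looked up that is not present in the ontology."""


class GmtFormatError(GsnamerError):
    """Malformed GMT document; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ResponseParseError(GsnamerError):
    """An LLM response could not be parsed; carries the raw text."""

    def __init__(self, message: str, raw: str = ""):
        self.raw = raw
        super().__init__(message)


class BackendError(GsnamerError):
    """An LLM or embedding backend failed after exhausting retries."""


class SimilarityError(GsnamerError):
    """Numeric failure in similarity computation (e.g. zero-norm embedding)."""


class BenchmarkError(GsnamerError):
    """Benchmark set construction failed (e.g. background pool too small)."""


class DegenerateTableError(GsnamerError):
    """A contingency table has too few informative columns to test."""
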