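"""Exception hierarchy shared across the package."""

from __future__ import annotations


class TermforgeError(Exception):
    """Base class for all errors raised by this package."""


class PatternError(TermforgeError):
    """Base class for pattern-language errors."""


class PatternSyntaxError(PatternError):
    """Raised when pattern source text cannot be parsed.

    Carries the 1-based line/column of the offending token and the set of
    token descriptions the parser would have accepted there.
    """

    def __init__(self, message: str, line: int, column: int,
                 expected: tuple[str, ...] = ()):
        self.line = line
        self.column = column
        self.expected = tuple(expected)
        loc = f"line {line}, column {column}"
        if expected:
            message = f"{message} at {loc} (expected one of: {', '.join(expected)})"
        else:
            message = f"{message} at {loc}"
        super().__init__(message)


class UndeclaredVariableError(PatternError):
    """A pattern action references a variable never declared."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"undeclared variable ?{name}")


class DuplicateDeclarationError(PatternError):
    """The same variable name is declared twice in one pattern."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"duplicate declaration of variable ?{name}")


class UnsupportedConstructError(PatternError):
    """A full-OPPL construct outside the supported ADD subset was used."""


class OntologyError(TermforgeError):
    """Ontology loading / querying failure."""


class UnknownEntityError(OntologyError):
    """A reference could not be resolved to any entity in the index."""

    def __init__(self, ref: str, message: str | None = None):
        self.ref = ref
        super().__init__(message or f"unknown entity reference: {ref!r}")


class AmbiguousLabelError(OntologyError):
    """A label resolves to more than one IRI."""

    def __init__(self, label: str, candidates: tuple[str, ...]):
        self.label = label
        self.candidates = tuple(sorted(candidates))
        super().__init__(
            f"label {label!r} is ambiguous between: {', '.join(self.candidates)}")


class TemplateError(TermforgeError):
    """Template schema violation or internal inconsistency."""


class SubmissionError(TermforgeError):
    """Structural problem with a submission (header mismatch etc.)."""


class ProcessingError(TermforgeError):
    """Row-level processing failed in fail-fast mode."""


class MintingError(TermforgeError):
    """IRI minting failed (collision, exhausted id space, minter failure)."""
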