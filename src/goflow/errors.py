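"""Exception hierarchy shared across the package."""


class GoflowError(Exception):
    """Base class for all package errors."""


class FlowchartLoadError(GoflowError):
    """A flowchart or prompts file failed to load or validate."""


class FlowchartUsageError(GoflowError):
    """A traversal operation was applied to the wrong node kind."""


class ArticleParseError(GoflowError):
    """Full-text XML could not be parsed into an article."""

    def __init__(self, message: str, pmcid: str | None = None):
        super().__init__(message)
        self.pmcid = pmcid


class ContractViolation(GoflowError):
    """A backend response broke the constrained-generation contract.

    Raised by the shared verifier wrapper, never silently repaired: an
    off-list choice or a span that is not a verbatim slice of its source
    must surface before reaching the curation engine.
    """

    def __init__(self, message: str, backend: str = "unknown"):
        super().__init__(f"[backend={backend}] {message}")
        self.backend = backend


class ScriptError(GoflowError):
    """A scripted backend was asked for a key it has no answer for."""


class BudgetExhausted(GoflowError):
    """The context-token budget cannot accommodate another section load."""


class LookupTableError(GoflowError):
    """An identifier lookup table is malformed (bad ids, duplicate keys)."""


class GeneListParseError(GoflowError):
    """A gene-mention payload does not match the annotations-API shape."""

    def __init__(self, message: str, path: str = ""):
        super().__init__(f"{message} (at {path})" if path else message)
        self.path = path


class IntegrityError(GoflowError):
    """A curation record is internally inconsistent."""


class SpecificityError(IntegrityError):
    """A record carries the bare parent GO term although its recorded
    answers replay to a more specific child term."""


class SpecError(GoflowError):
    """A synthetic-article specification is contradictory."""
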