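"""Exception hierarchy shared across the package."""


class GenesumError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GenesumError):
    """An input file does not parse in its stated dialect."""


class OntologyValidationError(GenesumError):
    """An ontology violates a structural invariant (e.g. a cycle)."""

    def __init__(self, message: str, cycle=None):
        super().__init__(message)
        self.cycle = list(cycle) if cycle is not None else None


class UnknownTermError(GenesumError, KeyError):
    """A term identifier is not present in the ontology."""


class EmptyInputError(GenesumError):
    """An input that must be nonempty (gene set, annotation file) is empty."""


class MissingGenesError(GenesumError):
    """No gene of the query set is present in the background universe."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "no query gene found in the background universe; missing: "
            + ", ".join(self.missing)
        )


class BudgetError(GenesumError):
    """The prompt template alone exceeds the model token budget."""


class TransportError(GenesumError):
    """The completion backend failed and no cached response exists."""

    def __init__(self, message: str, retryable: bool = True):
        super().__init__(message)
        self.retryable = retryable


class PayloadParseError(GenesumError):
    """A completion payload has no recognizable term-list section."""

    def __init__(self, message: str, raw_text: str = ""):
        super().__init__(message)
        self.raw_text = raw_text


class FixtureSpecError(GenesumError):
    """A synthetic-fixture specification is internally infeasible."""
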