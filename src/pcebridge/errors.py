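"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`PcebridgeError`; the CLI maps each
branch of the hierarchy to a distinct exit code.
"""


class PcebridgeError(Exception):
    """Base class for all errors raised by this package."""


class TerminologyLoadError(PcebridgeError):
    """A release file is missing or unreadable."""


class TerminologyIntegrityError(PcebridgeError):
    """The loaded content violates a structural guarantee (cycle, dangling id)."""


class ConceptLookupError(PcebridgeError, KeyError):
    """An identifier is absent from (or inactive in) the terminology."""


class ExpressionSyntaxError(PcebridgeError):
    """Malformed compositional-grammar text."""

    def __init__(self, message: str, line: int = 1, column: int = 0, expected: str | None = None):
        detail = f"line {line}, column {column}: {message}"
        if expected:
            detail += f" (expected {expected})"
        super().__init__(detail)
        self.line = line
        self.column = column
        self.expected = expected


class NormalizationError(PcebridgeError):
    """Normalization exceeded the configured nesting/recursion depth."""


class EclSyntaxError(PcebridgeError):
    """Malformed expression-constraint text."""


class SimilarityDomainError(PcebridgeError, ValueError):
    """Similarity counts outside the admissible domain."""


class CategoryError(PcebridgeError):
    """A PCE matched zero content categories."""


class DisjointnessError(PcebridgeError):
    """Two content-category constraints overlap on the loaded terminology."""


class StructureMapSchemaError(PcebridgeError):
    """A StructureMap document violates the expected rule shape."""


class EmissionError(PcebridgeError):
    """A binding could not be written into a resource document."""


class ReverseMappingError(PcebridgeError):
    """A stored coding could not be traced back to a SNOMED attribute."""


class RecompositionError(PcebridgeError):
    """Recomposition is impossible (e.g. no Superconcept element present)."""


class FixtureSpecError(PcebridgeError):
    """An unsatisfiable synthetic-terminology specification."""


class CorpusError(PcebridgeError):
    """No semantically valid expression could be generated for a concept."""
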