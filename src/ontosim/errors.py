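"""Exception taxonomy shared by all ontosim modules.

Every error raised on a user-input or evaluation path derives from
:class:`OntosimError` so callers (and the CLI) can distinguish input
problems from programming errors.
"""


class OntosimError(Exception):
    """Base class for all ontosim errors."""


# --- ontology construction / lookup ---------------------------------------

class CycleError(OntosimError):
    """The parent relation contains a directed cycle; names one id on it."""


class DanglingParentError(OntosimError):
    """A term references a parent id absent from the term set."""


class MultipleRootsError(OntosimError):
    """A namespace does not have exactly one parentless term."""


class UnknownTermError(OntosimError, KeyError):
    """A term id is not present in the DAG."""


class NamespaceMismatchError(OntosimError):
    """Two terms being compared live in different namespaces."""


class NoCommonAncestorError(OntosimError):
    """A term pair shares no common ancestor."""


class ZeroCountError(OntosimError):
    """All common ancestors carry annotation count zero (no informative MICA)."""


class NoAnnotationsError(OntosimError):
    """Probabilities requested before any annotation reached the namespace root."""


# --- parsing (OBO / annotations / dialect files) ---------------------------

class EmptyFileError(OntosimError):
    """An ontology text contains no term stanza at all."""


class MissingIdError(OntosimError):
    """A term stanza closed without ever providing an id line."""


class MalformedLineError(OntosimError):
    """A column-mode annotation line has fewer columns than the spec needs."""


class OrderingError(OntosimError):
    """Session steps invoked out of order (annotations before the ontology)."""


# --- formula DSL ------------------------------------------------------------

class FormulaSyntaxError(OntosimError):
    """Formula text failed to parse; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnknownComponentError(OntosimError):
    """An identifier in a formula is not in the component registry."""


class DomainError(OntosimError):
    """log of a non-positive value, sqrt of a negative value, or a non-finite result."""


class DivisionByZeroError(OntosimError):
    """Division (or zero raised to a negative power) with a zero denominator."""


class ValidationError(OntosimError):
    """A definition dialogue produced an inconsistent algorithm."""


# --- algorithm store / gene store -------------------------------------------

class DuplicateNameError(OntosimError):
    """An algorithm with this name already exists in the store."""


class NotFoundError(OntosimError):
    """No stored algorithm under the requested name."""


class CorruptFileError(OntosimError):
    """A stored algorithm or spec file is missing a mandatory key."""


class UnknownGeneError(OntosimError, KeyError):
    """A gene id is not present in the gene-product store."""


class EmptyTermSetError(OntosimError):
    """Namespace filtering removed every term annotated to a gene."""


class AllPairsFailedError(OntosimError):
    """Every term pair of a gene comparison raised a domain error."""
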