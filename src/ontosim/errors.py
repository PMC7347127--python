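"""Exception hierarchy.

Usage errors (bad flags, unknown measure names) are raised by the CLI layer
directly; everything here signals a problem with the *data* and maps to
exit code 1 in the CLI.
"""


class OntosimError(Exception):
    """Base class for all data errors raised by this package."""


class OboParseError(OntosimError):
    """Structurally invalid OBO input (e.g. a [Term] stanza without an id)."""


class CycleError(OboParseError):
    """The subsumption graph contains a directed cycle."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"ontology graph is cyclic; term {member!r} lies on a cycle")


class UnknownTermError(OntosimError):
    """A term id that does not resolve in the ontology."""


class UnannotatedEntityError(OntosimError):
    """An entity with no (usable) annotation in the corpus."""


class CrossNamespaceError(OntosimError):
    """An operation mixing terms from different namespaces."""


class UndefinedICError(OntosimError):
    """A node-based measure touched a term never annotated in the corpus."""


class EmptyInputError(OntosimError):
    """An operation received an empty corpus, set or matrix."""
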