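"""Core in-memory containers: ontology DAG and annotation corpus.

The ontology is a rooted directed acyclic graph of terms.  Edges point
child -> parent and carry a relation label; only ``is_a`` and ``part_of``
edges participate in traversal (ancestor closure, depth, information
content) — the subsumption relations used by GO-, HPO- and DO-style
ontologies.  Other relation types are kept for inspection but are inert.

Annotations attach entities (genes, diseases, phenotypes ...) to terms.
Under the true-path rule an annotation to a term implies annotation to all
of its ancestors, so the corpus stores both the direct term sets and their
ancestor closure ("propagated" sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import CrossNamespaceError, UnknownTermError

#: Relations that define subsumption and are followed by all graph traversals.
TRAVERSAL_RELATIONS = ("is_a", "part_of")


@dataclass
class TermRecord:
    """One ontology term."""

    id: str
    name: str = ""
    namespace: str = ""
    is_obsolete: bool = False
    #: (parent_id, relation) pairs; empty for obsolete terms and roots.
    parents: list[tuple[str, str]] = field(default_factory=list)
    alt_ids: list[str] = field(default_factory=list)


class OntologyGraph:
    """A parsed, validated OBO ontology.

    Parameters
    ----------
    terms
        Map id -> :class:`TermRecord` for every *non-obsolete* term.
    edges
        Set of ``(child, parent, relation)`` triples over non-obsolete terms.
    alt_id_index
        Map from alternative/secondary ids (including ids of obsolete terms)
        to the canonical live id, or ``None`` when no live replacement exists.
    """

    def __init__(
        self,
        terms: dict[str, TermRecord],
        edges: set[tuple[str, str, str]],
        alt_id_index: dict[str, str | None] | None = None,
    ):
        self.terms = terms
        self.edges = edges
        self.alt_id_index = dict(alt_id_index or {})

        # child -> parent digraph restricted to subsumption relations
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent, rel in edges:
            if rel in TRAVERSAL_RELATIONS:
                g.add_edge(child, parent, relation=rel)
        self._traversal = g

        self.roots: dict[str, str] = {}
        for tid, rec in terms.items():
            if g.out_degree(tid) == 0:
                self.roots[rec.namespace] = tid

    # -- lookups ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def traversal(self) -> nx.DiGraph:
        """Child -> parent digraph over ``is_a`` and ``part_of`` edges."""
        return self._traversal

    def resolve(self, term_id: str) -> str | None:
        """Map an id (possibly an alt id or an obsolete id) to a live term.

        Returns ``None`` when the id is known but has no live target
        (an obsolete term without a replacement); raises
        :class:`UnknownTermError` when the id is entirely unknown.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_id_index:
            return self.alt_id_index[term_id]
        raise UnknownTermError(f"unknown term id {term_id!r}")

    def namespace_of(self, term_id: str) -> str:
        if term_id not in self.terms:
            raise UnknownTermError(f"unknown term id {term_id!r}")
        return self.terms[term_id].namespace

    def require_same_namespace(self, *term_ids: str) -> str:
        """Return the shared namespace of the given terms or raise."""
        namespaces = {self.namespace_of(t) for t in term_ids}
        if len(namespaces) > 1:
            raise CrossNamespaceError(
                f"terms {sorted(term_ids)} span namespaces {sorted(namespaces)}"
            )
        return namespaces.pop()

    def namespace_terms(self, namespace: str) -> set[str]:
        return {t for t, r in self.terms.items() if r.namespace == namespace}

    def root_of(self, namespace: str) -> str:
        if namespace not in self.roots:
            raise UnknownTermError(f"no root for namespace {namespace!r}")
        return self.roots[namespace]


@dataclass
class AnnotationCorpus:
    """Entity -> term annotations, direct and ancestor-closed.

    ``direct`` keeps ``(term_id, evidence_code)`` pairs (evidence may be the
    empty string); ``propagated`` is the union of inclusive ancestor sets of
    the direct terms, per the true-path rule.
    """

    graph: OntologyGraph
    direct: dict[str, set[tuple[str, str]]]
    propagated: dict[str, set[str]]
    #: Lines dropped during parsing, keyed by reason (for user warnings).
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def entity_universe(self) -> set[str]:
        return set(self.direct)

    @property
    def term_universe(self) -> set[str]:
        """All terms directly used by at least one entity."""
        return {t for terms in self.direct.values() for t, _ in terms}

    def direct_terms(self, entity: str, namespace: str | None = None) -> set[str]:
        terms = {t for t, _ in self.direct.get(entity, set())}
        if namespace is not None:
            terms = {t for t in terms if self.graph.namespace_of(t) == namespace}
        return terms

    def propagated_terms(self, entity: str, namespace: str | None = None) -> set[str]:
        terms = set(self.propagated.get(entity, set()))
        if namespace is not None:
            terms = {t for t in terms if self.graph.namespace_of(t) == namespace}
        return terms

    def annotated_entities(self, namespace: str | None = None) -> set[str]:
        """Entities with at least one direct annotation (in ``namespace``)."""
        return {e for e in self.direct if self.direct_terms(e, namespace)}
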