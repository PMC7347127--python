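"""DAG algorithms over the ontology and corpus-based information content.

Information content (IC) of a term is the negative natural log of its
annotation probability: ``IC(t) = -ln p(t)`` with
``p(t) = counts[t] / counts[root]`` where ``counts[t]`` is the number of
*distinct entities* annotated (after propagation) to ``t`` or any of its
descendants.  The root is always annotated by every entity in its
namespace, so ``p(root) = 1`` and ``IC(root) = 0``; IC grows monotonically
with specificity along subsumption edges.

Terms never annotated in the corpus have *undefined* IC (not zero, not
infinite); node-based similarity measures touching one raise
:class:`~ontosim.errors.UndefinedICError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .errors import EmptyInputError, UndefinedICError, UnknownTermError
from .ontology import AnnotationCorpus, OntologyGraph


# ---------------------------------------------------------------------------
# Closure / depth
# ---------------------------------------------------------------------------

def ancestors(graph: OntologyGraph, term: str, inclusive: bool = False) -> set[str]:
    """Transitive closure of ``term`` over child -> parent traversal edges."""
    if term not in graph:
        raise UnknownTermError(f"unknown term id {term!r}")
    anc = nx.descendants(graph.traversal, term)
    if inclusive:
        anc = anc | {term}
    return anc


def descendants(graph: OntologyGraph, term: str, inclusive: bool = False) -> set[str]:
    """All terms subsumed by ``term`` (children-of-children ...)."""
    if term not in graph:
        raise UnknownTermError(f"unknown term id {term!r}")
    desc = nx.ancestors(graph.traversal, term)
    if inclusive:
        desc = desc | {term}
    return desc


def depth(graph: OntologyGraph, term: str) -> int:
    """Minimum number of traversal edges from ``term`` to its namespace root."""
    root = graph.root_of(graph.namespace_of(term))
    d = path_length(graph, term, root)
    if d is None:
        raise UnknownTermError(f"term {term!r} does not reach root {root!r}")
    return d


def path_length(graph: OntologyGraph, term: str, ancestor: str) -> int | None:
    """Shortest directed path length term -> ancestor, or None if unreachable."""
    try:
        return nx.shortest_path_length(graph.traversal, term, ancestor)
    except nx.NetworkXNoPath:
        return None


# ---------------------------------------------------------------------------
# Common ancestors
# ---------------------------------------------------------------------------

def common_ancestors(graph: OntologyGraph, t1: str, t2: str) -> set[str]:
    """Inclusive-ancestor intersection, so ``common_ancestors(t, t) ∋ t``."""
    graph.require_same_namespace(t1, t2)
    return ancestors(graph, t1, inclusive=True) & ancestors(graph, t2, inclusive=True)


def mica(graph: OntologyGraph, ic: "ICTable", t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor and its IC.

    Ties on IC break to the lexicographically smallest id so that exported
    matrices are reproducible.
    """
    ca = common_ancestors(graph, t1, t2)
    best = min(ca, key=lambda t: (-ic[t], t))
    return best, ic[best]


def dca(graph: OntologyGraph, t1: str, t2: str) -> set[str]:
    """Disjoint common ancestors: common ancestors that subsume no other.

    Keeps only the most specific members of the common-ancestor set — any
    term that is a strict ancestor of another common ancestor is removed.
    """
    ca = common_ancestors(graph, t1, t2)
    return {a for a in ca if not (descendants(graph, a) & ca)}


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

@dataclass
class ICTable:
    """Per-term annotation counts, probabilities and information content."""

    namespace: str
    counts: dict[str, int]
    total: int
    p: dict[str, float]
    ic: dict[str, float]

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise UndefinedICError(
                f"term {term!r} has no corpus annotation; its IC is undefined"
            ) from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def prob(self, term: str) -> float:
        try:
            return self.p[term]
        except KeyError:
            raise UndefinedICError(
                f"term {term!r} has no corpus annotation; its p is undefined"
            ) from None

    @property
    def max_ic(self) -> float:
        return max(self.ic.values())

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("term\tcount\tp\tic\n")
            for t in sorted(self.ic):
                fh.write(f"{t}\t{self.counts[t]}\t{self.p[t]:.6f}\t{self.ic[t]:.6f}\n")


def compute_ic(
    graph: OntologyGraph, corpus: AnnotationCorpus, namespace: str | None = None
) -> ICTable:
    """Estimate p(t) and IC(t) from a propagated annotation corpus.

    ``counts[t]`` is the number of distinct entities whose propagated set
    contains ``t`` — a union over the sub-DAG, never a sum over children,
    so multiple inheritance cannot double-count an entity.
    """
    if namespace is None:
        if len(graph.roots) != 1:
            raise EmptyInputError(
                f"ontology has namespaces {sorted(graph.roots)}; pick one"
            )
        namespace = next(iter(graph.roots))
    root = graph.root_of(namespace)

    counts: dict[str, int] = {}
    for entity in corpus.propagated:
        for t in corpus.propagated_terms(entity, namespace):
            counts[t] = counts.get(t, 0) + 1
    if not counts:
        raise EmptyInputError(f"no entity is annotated in namespace {namespace!r}")

    total = counts[root]
    p = {t: c / total for t, c in counts.items()}
    ic = {t: -math.log(pt) for t, pt in p.items()}
    ic[root] = 0.0  # avoid -0.0
    return ICTable(namespace=namespace, counts=counts, total=total, p=p, ic=ic)
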