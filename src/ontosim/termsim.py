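"""Between-term semantic similarity measures.

Eleven measures in three families:

* node-based, driven by corpus information content — Resnik, Lin,
  Jiang–Conrath (JC) and Schlicker's relevance (Rel), each in a MICA
  variant (most informative common ancestor) and a GraSM variant that
  averages the IC over all *disjoint* common ancestors;
* edge-based, driven by path lengths in the DAG — Wu2005 (depth ratio at
  the deepest common ancestor) and Yu2005 (inverse shortest common-ancestor
  path);
* hybrid — Wang2007, which aggregates per-relation semantic contributions
  (S-values) over each term's ancestor subgraph.

All measures are symmetric.  Lin, JC, Rel, Wu2005, Yu2005 and Wang2007 are
bounded in [0, 1]; Resnik is unbounded in IC units unless
``normalize_resnik`` is set.
"""

from __future__ import annotations

import math
import statistics

import networkx as nx
import numpy as np

from .errors import OntosimError
from .graph import ICTable, ancestors, common_ancestors, dca, depth, mica, path_length
from .matrix import SimilarityMatrix, TermMeasureConfig
from .ontology import OntologyGraph

__all__ = [
    "sim_resnik", "sim_lin", "sim_jc", "sim_rel", "sim_grasm",
    "sim_wu2005", "sim_yu2005", "sim_wang2007", "sim_term", "term_matrix",
]


# ---------------------------------------------------------------------------
# Node-based (MICA)
# ---------------------------------------------------------------------------

def sim_resnik(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor."""
    return mica(graph, ic, t1, t2)[1]


def _lin_from_shared(shared_ic: float, ic1: float, ic2: float, same: bool) -> float:
    denom = ic1 + ic2
    if denom == 0.0:
        # both terms are as general as the root: identical pairs are maximally
        # similar by convention, distinct ones share nothing informative
        return 1.0 if same else 0.0
    return 2.0 * shared_ic / denom


def sim_lin(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """2·IC(MICA) / (IC(t1) + IC(t2)), in [0, 1]."""
    return _lin_from_shared(sim_resnik(graph, ic, t1, t2), ic[t1], ic[t2], t1 == t2)


def sim_jc(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """Jiang–Conrath, as the bounded similarity 1 / (1 + d_JC).

    ``d_JC = IC(t1) + IC(t2) - 2·IC(MICA)`` is the Jiang–Conrath semantic
    distance; the ``1/(1+d)`` transform maps it monotonically onto (0, 1].
    """
    d = ic[t1] + ic[t2] - 2.0 * sim_resnik(graph, ic, t1, t2)
    return 1.0 / (1.0 + max(d, 0.0))


def sim_rel(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """Schlicker relevance: Lin weighted by (1 - p(MICA))."""
    a, shared_ic = mica(graph, ic, t1, t2)
    lin = _lin_from_shared(shared_ic, ic[t1], ic[t2], t1 == t2)
    return lin * (1.0 - ic.prob(a))


# ---------------------------------------------------------------------------
# Node-based (GraSM): average IC over disjoint common ancestors
# ---------------------------------------------------------------------------

def _share(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    return statistics.fmean(ic[a] for a in dca(graph, t1, t2))


def sim_grasm(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str, base: str = "resnik"
) -> float:
    """GraSM variant of a node-based measure.

    Replaces IC(MICA) with ``share(t1,t2)``, the arithmetic mean IC over
    the disjoint common ancestors; for ``rel`` the probability of the MICA
    is correspondingly replaced by ``exp(-share)``.
    """
    share = _share(graph, ic, t1, t2)
    if base == "resnik":
        return share
    if base == "lin":
        return _lin_from_shared(share, ic[t1], ic[t2], t1 == t2)
    if base == "jc":
        d = ic[t1] + ic[t2] - 2.0 * share
        return 1.0 / (1.0 + max(d, 0.0))
    if base == "rel":
        lin = _lin_from_shared(share, ic[t1], ic[t2], t1 == t2)
        return lin * (1.0 - math.exp(-share))
    raise ValueError(f"unknown GraSM base {base!r}")


# ---------------------------------------------------------------------------
# Edge-based
# ---------------------------------------------------------------------------

def sim_wu2005(graph: OntologyGraph, t1: str, t2: str) -> float:
    """Depth ratio at the deepest common ancestor.

    With ``a`` the common ancestor of maximal depth (ties broken by the
    smaller summed path length, then lexicographically)::

        sim = 2·depth(a) / (len(t1->a) + len(t2->a) + 2·depth(a))

    The root-only pair (root, root) is defined as 1.
    """
    best = None
    for a in common_ancestors(graph, t1, t2):
        key = (-depth(graph, a),
               path_length(graph, t1, a) + path_length(graph, t2, a),
               a)
        if best is None or key < best:
            best = key
    neg_d, lsum, _ = best
    d = -neg_d
    denom = lsum + 2 * d
    return 1.0 if denom == 0 else 2.0 * d / denom


def sim_yu2005(graph: OntologyGraph, t1: str, t2: str) -> float:
    """Inverse path length: 1 / (1 + d) with d the shortest path between
    the terms through any common ancestor."""
    d = min(
        path_length(graph, t1, a) + path_length(graph, t2, a)
        for a in common_ancestors(graph, t1, t2)
    )
    return 1.0 / (1.0 + d)


# ---------------------------------------------------------------------------
# Hybrid (Wang 2007)
# ---------------------------------------------------------------------------

def _svalues(
    graph: OntologyGraph, term: str, weights: dict[str, float]
) -> dict[str, float]:
    """Semantic contribution of each ancestor of ``term`` to ``term``.

    ``S_t(t) = 1``; walking child -> parent, each ancestor receives the
    best weighted contribution among its children inside the term's
    inclusive-ancestor subgraph.
    """
    sub = graph.traversal.subgraph(ancestors(graph, term, inclusive=True))
    s = {term: 1.0}
    for node in nx.topological_sort(sub):  # children before parents
        if node == term:
            continue
        best = 0.0
        for child, _, rel in sub.in_edges(node, data="relation"):
            if rel not in weights:
                raise OntosimError(
                    f"no semantic contribution factor configured for relation {rel!r}"
                )
            best = max(best, weights[rel] * s[child])
        s[node] = best
    return s


def sim_wang2007(
    graph: OntologyGraph,
    t1: str,
    t2: str,
    weights: dict[str, float] | None = None,
) -> float:
    """Wang's hybrid measure over aggregated S-values."""
    if weights is None:
        weights = {"is_a": 0.8, "part_of": 0.6}
    graph.require_same_namespace(t1, t2)
    s1 = _svalues(graph, t1, weights)
    s2 = _svalues(graph, t2, weights)
    shared = s1.keys() & s2.keys()
    return sum(s1[a] + s2[a] for a in shared) / (sum(s1.values()) + sum(s2.values()))


# ---------------------------------------------------------------------------
# Dispatch / matrices
# ---------------------------------------------------------------------------

def sim_term(
    graph: OntologyGraph,
    t1: str,
    t2: str,
    config: TermMeasureConfig,
    ic: ICTable | None = None,
) -> float:
    """Similarity between two terms under the configured measure."""
    name = config.name
    if name in ("wu2005", "yu2005", "wang2007"):
        if name == "wu2005":
            return sim_wu2005(graph, t1, t2)
        if name == "yu2005":
            return sim_yu2005(graph, t1, t2)
        return sim_wang2007(graph, t1, t2, config.wang_weights)
    if ic is None:
        raise OntosimError(f"measure {name!r} needs an information-content table")
    if name.endswith("_grasm"):
        return sim_grasm(graph, ic, t1, t2, base=name[: -len("_grasm")])
    score = {"resnik": sim_resnik, "lin": sim_lin, "jc": sim_jc, "rel": sim_rel}[name](
        graph, ic, t1, t2
    )
    if name == "resnik" and config.normalize_resnik:
        score /= ic.max_ic
    return score


def term_matrix(
    terms: list[str],
    config: TermMeasureConfig,
    graph: OntologyGraph,
    ic: ICTable | None = None,
) -> SimilarityMatrix:
    """Symmetric similarity matrix over the given term order."""
    n = len(terms)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = sim_term(graph, terms[i], terms[j], config, ic)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(list(terms), list(terms), values, measure=config.name)
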