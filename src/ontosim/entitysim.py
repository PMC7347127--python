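"""Between-entity functional similarity.

Two families:

* **pairwise** — build the term-term similarity matrix between the two
  entities' direct annotation sets under a between-term measure, then
  combine it with Avg, Max, best-match-average (BMA) or rcMax;
* **groupwise** — compare whole annotation sets directly: term overlap
  (TO), normalised term overlap (NTO), union-intersection / simUI (UI),
  longest shared path depth (LP) and IC-weighted simGIC on ancestor-closed
  ("extended") sets, plus cosine and Cohen's kappa on binary direct-term
  vectors over the corpus term universe.

Graph-based measures default to extended sets because subsumption makes an
annotation to a term an implicit annotation to its ancestors; vector-based
measures default to direct sets so the agreement universe stays the set of
terms the corpus actually uses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    CrossNamespaceError,
    EmptyInputError,
    UnannotatedEntityError,
)
from .graph import ICTable, depth
from .matrix import SimilarityMatrix, TermMeasureConfig
from .ontology import AnnotationCorpus
from .termsim import sim_term

log = logging.getLogger(__name__)

PAIRWISE_MODES = ("avg", "max", "bma", "rcmax")
GROUPWISE_MEASURES = ("to", "nto", "ui", "lp", "gic", "cosine", "kappa")
ENTITY_MEASURES = PAIRWISE_MODES + GROUPWISE_MEASURES

#: measures whose natural annotation view is the ancestor-closed set
_EXTENDED_DEFAULT = {"to", "nto", "ui", "lp", "gic"}


@dataclass
class EntityMeasureConfig:
    """Selection of a between-entity measure.

    ``term_config`` is required for the pairwise modes and ignored by the
    groupwise ones; ``annotation_view`` overrides the per-measure default
    (extended sets for graph-based measures, direct sets for vector-based).
    """

    name: str = "bma"
    term_config: TermMeasureConfig | None = None
    annotation_view: str | None = None  # None = per-measure default

    def __post_init__(self):
        if self.name not in ENTITY_MEASURES:
            raise ValueError(
                f"unknown entity measure {self.name!r}; "
                f"choose from {sorted(ENTITY_MEASURES)}"
            )
        if self.name in PAIRWISE_MODES and self.term_config is None:
            self.term_config = TermMeasureConfig()
        if self.annotation_view not in (None, "direct", "extended"):
            raise ValueError("annotation_view must be 'direct' or 'extended'")

    @property
    def view(self) -> str:
        if self.annotation_view is not None:
            return self.annotation_view
        return "extended" if self.name in _EXTENDED_DEFAULT else "direct"

    @property
    def label(self) -> str:
        if self.name in PAIRWISE_MODES:
            return f"{self.name}({self.term_config.name})"
        return self.name


# ---------------------------------------------------------------------------
# Pairwise combiners
# ---------------------------------------------------------------------------

def pairwise_combine(scores: np.ndarray, mode: str) -> float:
    """Combine an n×m term-term score matrix into one entity-level score.

    avg and max pool every cell; BMA averages the row-wise and column-wise
    best matches; rcMax takes the larger of the two best-match row/column
    means.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise EmptyInputError("cannot combine an empty score matrix")
    if mode == "avg":
        return float(s.mean())
    if mode == "max":
        return float(s.max())
    row_best = s.max(axis=1)
    col_best = s.max(axis=0)
    if mode == "bma":
        return float((row_best.sum() + col_best.sum()) / (s.shape[0] + s.shape[1]))
    if mode == "rcmax":
        return float(max(row_best.mean(), col_best.mean()))
    raise ValueError(f"unknown pairwise mode {mode!r}")


def entity_sim_pairwise(
    e1: str,
    e2: str,
    corpus: AnnotationCorpus,
    config: EntityMeasureConfig,
    ic: ICTable | None = None,
    namespace: str | None = None,
) -> float:
    namespace = _shared_namespace(corpus, e1, e2, namespace)
    t1 = _term_view(corpus, e1, "direct", namespace)
    t2 = _term_view(corpus, e2, "direct", namespace)
    graph = corpus.graph
    scores = np.array(
        [[sim_term(graph, a, b, config.term_config, ic) for b in sorted(t2)]
         for a in sorted(t1)]
    )
    return pairwise_combine(scores, config.name)


# ---------------------------------------------------------------------------
# Groupwise measures
# ---------------------------------------------------------------------------

def groupwise_to(x1: set[str], x2: set[str]) -> float:
    """Raw term overlap |X1 ∩ X2| (unbounded)."""
    return float(len(x1 & x2))


def groupwise_nto(x1: set[str], x2: set[str]) -> float:
    """Term overlap normalised by the smaller set."""
    return len(x1 & x2) / min(len(x1), len(x2))


def groupwise_ui(x1: set[str], x2: set[str]) -> float:
    """Union–intersection (Jaccard) similarity, a.k.a. simUI."""
    return len(x1 & x2) / len(x1 | x2)


def groupwise_lp(x1: set[str], x2: set[str], corpus: AnnotationCorpus) -> float:
    """Depth of the deepest shared term (longest path; unbounded integer)."""
    return float(max(depth(corpus.graph, t) for t in x1 & x2))


def groupwise_gic(x1: set[str], x2: set[str], ic: ICTable) -> float:
    """simGIC: IC-weighted Jaccard over the extended sets."""
    num = sum(ic[t] for t in x1 & x2)
    den = sum(ic[t] for t in x1 | x2)
    return num / den if den else 1.0


def groupwise_cosine(t1: set[str], t2: set[str]) -> float:
    """Cosine of the binary annotation vectors: |T1∩T2| / sqrt(|T1|·|T2|)."""
    return len(t1 & t2) / math.sqrt(len(t1) * len(t2))


def groupwise_kappa(t1: set[str], t2: set[str], universe_size: int) -> float:
    """Cohen's kappa of the binary annotation vectors over the term universe.

    Chance agreement ``p_e`` follows the standard 2×2 agreement table; the
    degenerate ``p_e = 1`` case (both vectors constant) is scored 1 for
    identical sets and 0 otherwise.
    """
    m = universe_size
    inter = len(t1 & t2)
    union = len(t1 | t2)
    p_o = (inter + (m - union)) / m
    f1, f2 = len(t1) / m, len(t2) / m
    p_e = f1 * f2 + (1 - f1) * (1 - f2)
    if p_e == 1.0:
        return 1.0 if t1 == t2 else 0.0
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# Dispatch / matrices
# ---------------------------------------------------------------------------

def _shared_namespace(
    corpus: AnnotationCorpus, e1: str, e2: str, namespace: str | None
) -> str:
    if namespace is not None:
        return namespace
    graph = corpus.graph
    ns1 = {graph.namespace_of(t) for t in corpus.direct_terms(e1)}
    ns2 = {graph.namespace_of(t) for t in corpus.direct_terms(e2)}
    shared = ns1 & ns2
    if not shared:
        if not ns1:
            raise UnannotatedEntityError(f"entity {e1!r} has no annotation")
        if not ns2:
            raise UnannotatedEntityError(f"entity {e2!r} has no annotation")
        raise CrossNamespaceError(
            f"entities {e1!r} and {e2!r} are annotated in disjoint namespaces"
        )
    if len(shared) > 1:
        raise CrossNamespaceError(
            f"entities {e1!r}, {e2!r} share namespaces {sorted(shared)}; pick one"
        )
    return shared.pop()


def _term_view(
    corpus: AnnotationCorpus, entity: str, view: str, namespace: str
) -> set[str]:
    getter = corpus.direct_terms if view == "direct" else corpus.propagated_terms
    terms = getter(entity, namespace)
    if not terms:
        raise UnannotatedEntityError(
            f"entity {entity!r} has no annotation in namespace {namespace!r}"
        )
    return terms


def _vector_universe(
    corpus: AnnotationCorpus, view: str, namespace: str
) -> set[str]:
    graph = corpus.graph
    if view == "direct":
        terms = corpus.term_universe
    else:
        terms = {t for e in corpus.direct for t in corpus.propagated_terms(e)}
    return {t for t in terms if graph.namespace_of(t) == namespace}


def sim_entity(
    e1: str,
    e2: str,
    corpus: AnnotationCorpus,
    config: EntityMeasureConfig,
    ic: ICTable | None = None,
    namespace: str | None = None,
) -> float:
    """Similarity between two annotated entities under the configured measure."""
    if config.name in PAIRWISE_MODES:
        return entity_sim_pairwise(e1, e2, corpus, config, ic, namespace)
    namespace = _shared_namespace(corpus, e1, e2, namespace)
    x1 = _term_view(corpus, e1, config.view, namespace)
    x2 = _term_view(corpus, e2, config.view, namespace)
    name = config.name
    if name == "to":
        return groupwise_to(x1, x2)
    if name == "nto":
        return groupwise_nto(x1, x2)
    if name == "ui":
        return groupwise_ui(x1, x2)
    if name == "lp":
        return groupwise_lp(x1, x2, corpus)
    if name == "gic":
        if ic is None:
            raise EmptyInputError("gic needs an information-content table")
        return groupwise_gic(x1, x2, ic)
    universe = _vector_universe(corpus, config.view, namespace)
    if name == "cosine":
        return groupwise_cosine(x1, x2)
    return groupwise_kappa(x1, x2, len(universe))


def entity_matrix(
    entities: list[str],
    corpus: AnnotationCorpus,
    config: EntityMeasureConfig,
    ic: ICTable | None = None,
    namespace: str | None = None,
    strict: bool = False,
) -> SimilarityMatrix:
    """Symmetric entity similarity matrix.

    Entities without usable annotation are dropped with a warning, or
    rejected outright when ``strict`` is set.
    """
    kept = []
    for e in entities:
        if corpus.direct_terms(e, namespace):
            kept.append(e)
        elif strict:
            raise UnannotatedEntityError(f"entity {e!r} has no annotation")
        else:
            log.warning("entity_matrix: dropping unannotated entity %r", e)
    if not kept:
        raise EmptyInputError("no annotated entity left to compare")
    n = len(kept)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = sim_entity(kept[i], kept[j], corpus, config, ic, namespace)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(list(kept), list(kept), values, measure=config.label)
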