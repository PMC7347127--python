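"""Functional-similarity networks.

Turn a symmetric entity similarity matrix into an undirected weighted edge
list by keeping pairs whose score falls inside a closed [min, max]
threshold window; weigh an imported interaction network by the similarity
of its endpoints; and score the similarity of two entity sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, UnannotatedEntityError
from .entitysim import EntityMeasureConfig, pairwise_combine, sim_entity
from .graph import ICTable
from .matrix import SimilarityMatrix
from .ontology import AnnotationCorpus

log = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class WeightedEdge:
    """Undirected weighted edge; endpoints stored lexicographically."""

    source: str
    target: str
    weight: float

    @staticmethod
    def make(a: str, b: str, weight: float) -> "WeightedEdge":
        if a > b:
            a, b = b, a
        return WeightedEdge(a, b, weight)

    def astuple(self) -> tuple[str, str, float]:
        return (self.source, self.target, self.weight)


def similarity_network(
    matrix: SimilarityMatrix, min_t: float, max_t: float
) -> list[WeightedEdge]:
    """Edges for every unordered pair with min_t <= score <= max_t.

    Both thresholds are inclusive; the diagonal (self-similarity) is
    ignored.  Edges come back sorted for reproducible exports.
    """
    if min_t > max_t:
        raise ValueError(f"min threshold {min_t} exceeds max threshold {max_t}")
    if not matrix.is_square:
        raise ValueError("similarity_network needs a square labelled matrix")
    labels = matrix.row_labels
    edges = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            s = float(matrix.values[i, j])
            if min_t <= s <= max_t:
                edges.append(WeightedEdge.make(labels[i], labels[j], s))
    return sorted(edges)


def weigh_network(
    pairs: list[tuple[str, str]],
    corpus: AnnotationCorpus,
    config: EntityMeasureConfig,
    ic: ICTable | None = None,
    namespace: str | None = None,
    missing_policy: str = "drop",
) -> list[WeightedEdge]:
    """Re-emit an imported edge list weighted by endpoint similarity.

    Self-loops are dropped with a warning.  Edges with an unannotated
    endpoint are dropped (``missing_policy="drop"``, the default, with a
    warning count) or kept at weight zero (``"zero"``).
    """
    if missing_policy not in ("drop", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if not pairs:
        raise EmptyInputError("imported network has no edges")
    edges = []
    missing = self_loops = 0
    for a, b in pairs:
        if a == b:
            self_loops += 1
            continue
        try:
            w = sim_entity(a, b, corpus, config, ic, namespace)
        except UnannotatedEntityError:
            missing += 1
            if missing_policy == "zero":
                edges.append(WeightedEdge.make(a, b, 0.0))
            continue
        edges.append(WeightedEdge.make(a, b, w))
    if self_loops:
        log.warning("weigh_network: dropped %d self-loop(s)", self_loops)
    if missing:
        log.warning(
            "weigh_network: %d edge(s) had an unannotated endpoint (%s)",
            missing, missing_policy,
        )
    return edges


def set_similarity(
    set1: list[str],
    set2: list[str],
    corpus: AnnotationCorpus,
    config: EntityMeasureConfig,
    ic: ICTable | None = None,
    namespace: str | None = None,
    combine: str = "bma",
) -> float:
    """Similarity between two entity sets.

    Builds the |set1|×|set2| entity-similarity matrix under ``config`` and
    combines it — best-match average by default, which balances the two
    sets symmetrically; other pairwise combiners are available.
    """
    s1 = [e for e in dict.fromkeys(set1) if corpus.direct_terms(e, namespace)]
    s2 = [e for e in dict.fromkeys(set2) if corpus.direct_terms(e, namespace)]
    if not s1 or not s2:
        raise EmptyInputError("both entity sets need at least one annotated member")
    scores = np.array(
        [[sim_entity(a, b, corpus, config, ic, namespace) for b in s2] for a in s1]
    )
    return pairwise_combine(scores, combine)


def rescale_minmax(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Min-max rescale a matrix to [0, 1] (for thresholding raw TO/LP scores)."""
    v = matrix.values
    lo, hi = float(v.min()), float(v.max())
    scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    return SimilarityMatrix(
        list(matrix.row_labels), list(matrix.col_labels), scaled,
        measure=f"minmax({matrix.measure})",
    )
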