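"""Deterministic synthetic ontologies and annotation corpora.

Real ontology/annotation snapshots (GO, HPO, DO releases) are large and
versioned; every test and example in this package instead runs on
generated fixtures: random single-rooted DAGs serialised as valid OBO
text, and random annotation corpora over them.  Generation is driven by a
single seeded pseudo-random stream, so the same :class:`FixtureSpec`
always yields byte-identical files.

The module also hosts the five-term toy ontology (root R; A, B under R;
C, D under A) with a three-entity corpus used as the worked example
throughout the documentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import parse_annotations, parse_obo
from .ontology import AnnotationCorpus, OntologyGraph

EVIDENCE_CODES = ("EXP", "IEA", "TAS")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic ontology + corpus.

    ``part_of_fraction`` is the probability that a parent edge is
    ``part_of`` rather than ``is_a``; ``annotations_per_entity`` is an
    inclusive (low, high) range.  The seed is mandatory: identical specs
    produce identical bytes.
    """

    n_terms: int = 20
    n_entities: int = 10
    max_parents: int = 2
    part_of_fraction: float = 0.2
    annotations_per_entity: tuple[int, int] = (1, 3)
    with_evidence: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("need at least a root and one child term")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        lo, hi = self.annotations_per_entity
        if not 1 <= lo <= hi:
            raise ValueError("annotations_per_entity must be a range >= 1")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def make_dag(spec: FixtureSpec) -> tuple[OntologyGraph, str]:
    """Generate a random single-rooted DAG and its OBO serialisation.

    Terms are created in topological order; each non-root term draws 1 to
    ``max_parents`` distinct parents among the earlier terms, which makes
    the result acyclic by construction with a single parentless root.
    """
    rng = np.random.default_rng(spec.seed)
    lines = ["format-version: 1.2", "default-namespace: synthetic", ""]
    for i in range(spec.n_terms):
        tid = _term_id(i)
        lines += [f"[Term]", f"id: {tid}", f"name: synthetic term {i}"]
        if i > 0:
            k = min(int(rng.integers(1, spec.max_parents + 1)), i)
            parents = rng.choice(i, size=k, replace=False)
            for p in sorted(int(x) for x in parents):
                if rng.random() < spec.part_of_fraction:
                    lines.append(f"relationship: part_of {_term_id(p)}")
                else:
                    lines.append(f"is_a: {_term_id(p)}")
        lines.append("")
    obo_text = "\n".join(lines)
    return parse_obo_text(obo_text), obo_text


def make_corpus(graph: OntologyGraph, spec: FixtureSpec) -> str:
    """Generate annotation TSV text over a generated graph.

    Entities draw their annotation count uniformly from the configured
    range and their terms uniformly among non-root terms; evidence codes,
    when enabled, are sampled from EXP/IEA/TAS.
    """
    rng = np.random.default_rng(spec.seed + 1)
    roots = set(graph.roots.values())
    terms = sorted(t for t in graph.terms if t not in roots)
    lo, hi = spec.annotations_per_entity
    lines = []
    for i in range(spec.n_entities):
        entity = f"ent{i:04d}"
        k = min(int(rng.integers(lo, hi + 1)), len(terms))
        chosen = rng.choice(len(terms), size=k, replace=False)
        for idx in sorted(int(x) for x in chosen):
            if spec.with_evidence:
                ev = EVIDENCE_CODES[int(rng.integers(len(EVIDENCE_CODES)))]
                lines.append(f"{entity}\t{terms[idx]}\t{ev}")
            else:
                lines.append(f"{entity}\t{terms[idx]}")
    return "\n".join(lines) + "\n"


def make_fixture(spec: FixtureSpec) -> tuple[OntologyGraph, AnnotationCorpus]:
    """Convenience: generate and parse a graph + corpus pair."""
    graph, _ = make_dag(spec)
    corpus = parse_annotations_text(make_corpus(graph, spec), graph)
    return graph, corpus


# ---------------------------------------------------------------------------
# Text-based parse helpers (avoid temp files)
# ---------------------------------------------------------------------------

def parse_obo_text(text: str) -> OntologyGraph:
    import tempfile, os

    with tempfile.NamedTemporaryFile(
        "w", suffix=".obo", delete=False
    ) as fh:
        fh.write(text)
        path = fh.name
    try:
        return parse_obo(path)
    finally:
        os.unlink(path)


def parse_annotations_text(
    text: str, graph: OntologyGraph, evidence_filter: set[str] | None = None
) -> AnnotationCorpus:
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(text)
        path = fh.name
    try:
        return parse_annotations(path, graph, evidence_filter)
    finally:
        os.unlink(path)


# ---------------------------------------------------------------------------
# The worked-example toy ontology
# ---------------------------------------------------------------------------

TOY_OBO = """\
format-version: 1.2
default-namespace: toy

[Term]
id: R
name: root

[Term]
id: A
name: alpha
is_a: R

[Term]
id: B
name: beta
is_a: R

[Term]
id: C
name: gamma
is_a: A

[Term]
id: D
name: delta
is_a: A
"""

TOY_ANNOTATIONS = "e1\tC\ne2\tD\ne3\tB\n"


def toy5() -> tuple[OntologyGraph, AnnotationCorpus]:
    """The five-term worked-example ontology with its three-entity corpus.

    Terms R (root), A, B (children of R), C, D (children of A); entities
    e1 -> C, e2 -> D, e3 -> B.  Annotation counts after propagation are
    R:3, A:2, B:1, C:1, D:1, so IC(A) = ln(3/2) and IC(C) = ln 3.
    """
    graph = parse_obo_text(TOY_OBO)
    corpus = parse_annotations_text(TOY_ANNOTATIONS, graph)
    return graph, corpus
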