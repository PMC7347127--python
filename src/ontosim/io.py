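"""Reading OBO ontologies and annotation corpora; writing result tables.

The OBO reader delegates tokenisation of the flat-file format to
:mod:`obonet` and layers validation on top: stanzas must carry an ``id``,
the subsumption graph must be acyclic, and every namespace must have
exactly one root.  Obsolete terms are excluded from the graph but their
ids stay resolvable (to a ``replaced_by`` target when one is given).

Annotation corpora are plain TSV, one record per line::

    EntityID<tab>OntologyTermID[<tab>EvidenceCode]

The evidence code is optional; records without one are never removed by an
evidence filter (evidence is an attribute of an annotation, not a
requirement).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import networkx as nx
import obonet

from .errors import CycleError, EmptyInputError, OboParseError, UnknownTermError
from .ontology import TRAVERSAL_RELATIONS, AnnotationCorpus, OntologyGraph, TermRecord

if TYPE_CHECKING:  # pragma: no cover
    from .entitysim import SimilarityMatrix
    import pandas as pd

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# OBO ontologies
# ---------------------------------------------------------------------------

def _check_stanza_ids(text: str) -> None:
    """Raise :class:`OboParseError` (with a line number) for id-less stanzas."""
    stanza_line = None
    stanza_kind = None
    seen_id = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("[") and line.endswith("]"):
            if not seen_id:
                raise OboParseError(
                    f"{stanza_kind} stanza at line {stanza_line} has no id:"
                )
            stanza_line, stanza_kind = lineno, line
            seen_id = False
        elif line.startswith("id:"):
            seen_id = True
    if not seen_id:
        raise OboParseError(f"{stanza_kind} stanza at line {stanza_line} has no id:")


def _as_bool(value) -> bool:
    if isinstance(value, list):
        value = value[0] if value else "false"
    return str(value).strip().lower() == "true"


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into a validated :class:`OntologyGraph`.

    ``is_a`` and ``relationship: part_of`` lines become traversal edges;
    other relationship types are recorded with their label but are not
    followed.  Obsolete terms carry no edges and are only reachable through
    :meth:`OntologyGraph.resolve`.

    Raises
    ------
    OboParseError
        If a stanza lacks an ``id`` (the message names the line) or the
        file contains no ``[Term]`` stanza.
    CycleError
        If the subsumption graph has a directed cycle (names one member).
    """
    path = Path(path)
    _check_stanza_ids(path.read_text())

    raw = obonet.read_obo(path, ignore_obsolete=False)
    if len(raw) == 0:
        raise OboParseError(f"{path}: no [Term] stanzas found")
    default_ns = raw.graph.get("default-namespace", [""])
    if isinstance(default_ns, list):
        default_ns = default_ns[0] if default_ns else ""

    terms: dict[str, TermRecord] = {}
    obsolete: dict[str, dict] = {}
    for tid, data in raw.nodes(data=True):
        if _as_bool(data.get("is_obsolete", "false")):
            obsolete[tid] = data
            continue
        terms[tid] = TermRecord(
            id=tid,
            name=data.get("name", ""),
            namespace=data.get("namespace", default_ns),
            alt_ids=list(data.get("alt_id", [])),
        )

    edges: set[tuple[str, str, str]] = set()
    for child, parent, rel in raw.edges(keys=True):
        if child in terms and parent in terms:
            edges.add((child, parent, rel))
            terms[child].parents.append((parent, rel))

    alt_index: dict[str, str | None] = {}
    for tid, rec in terms.items():
        for alt in rec.alt_ids:
            alt_index[alt] = tid
    for tid, data in obsolete.items():
        replaced = data.get("replaced_by", [])
        alt_index[tid] = replaced[0] if replaced else None

    # cycle check on the subsumption relations only
    sub = nx.DiGraph(
        (c, p) for c, p, r in edges if r in TRAVERSAL_RELATIONS
    )
    if not nx.is_directed_acyclic_graph(sub):
        member = nx.find_cycle(sub)[0][0]
        raise CycleError(member)

    graph = OntologyGraph(terms, edges, alt_index)
    _validate_roots(graph)
    return graph


def _validate_roots(graph: OntologyGraph) -> None:
    by_ns: dict[str, list[str]] = {}
    for tid, rec in graph.terms.items():
        if graph.traversal.out_degree(tid) == 0:
            by_ns.setdefault(rec.namespace, []).append(tid)
    for ns, roots in by_ns.items():
        if len(roots) > 1:
            raise OboParseError(
                f"namespace {ns!r} has {len(roots)} parentless terms "
                f"({sorted(roots)[:5]} ...); expected a single root"
            )


# ---------------------------------------------------------------------------
# Annotation corpora
# ---------------------------------------------------------------------------

def parse_annotations(
    path: str | Path,
    graph: OntologyGraph,
    evidence_filter: set[str] | None = None,
) -> AnnotationCorpus:
    """Parse a 2/3-column TSV annotation corpus against a parsed ontology.

    Term ids are remapped through the ontology's alt-id index.  Lines whose
    term is unknown, obsolete without replacement, malformed (a single
    field) or filtered out by ``evidence_filter`` are skipped and counted
    in :attr:`AnnotationCorpus.skipped`; records with no evidence column
    pass every evidence filter.  Duplicate records are silently collapsed.

    Raises
    ------
    EmptyInputError
        If no record survives.
    """
    skipped = {"malformed": 0, "unknown_term": 0, "obsolete": 0, "evidence": 0}
    direct: dict[str, set[tuple[str, str]]] = {}

    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2:
            skipped["malformed"] += 1
            continue
        entity, term = fields[0].strip(), fields[1].strip()
        evidence = fields[2].strip() if len(fields) > 2 else ""
        if evidence_filter is not None and evidence and evidence not in evidence_filter:
            skipped["evidence"] += 1
            continue
        try:
            resolved = graph.resolve(term)
        except UnknownTermError:
            skipped["unknown_term"] += 1
            continue
        if resolved is None:
            skipped["obsolete"] += 1
            continue
        direct.setdefault(entity, set()).add((resolved, evidence))

    if not direct:
        raise EmptyInputError(f"{path}: no usable annotation records")
    dropped = {k: v for k, v in skipped.items() if v}
    if dropped:
        log.warning("parse_annotations(%s): skipped records %s", path, dropped)

    propagated = {
        entity: propagate({t for t, _ in pairs}, graph)
        for entity, pairs in direct.items()
    }
    return AnnotationCorpus(graph, direct, propagated, skipped=dropped)


def propagate(term_ids: Iterable[str], graph: OntologyGraph) -> set[str]:
    """Ancestor-close a term set over the subsumption edges (true-path rule)."""
    closed: set[str] = set()
    for t in term_ids:
        if t not in closed:
            closed.add(t)
            closed |= nx.descendants(graph.traversal, t)
    return closed


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: "SimilarityMatrix", path: str | Path) -> None:
    """Write a labelled similarity matrix as TSV.

    First line is a ``# measure:`` provenance comment, second the column
    labels; floats are fixed to 6 decimal places for reproducible diffs.
    """
    path = Path(path)
    with path.open("w") as fh:
        if matrix.measure:
            fh.write(f"# measure: {matrix.measure}\n")
        fh.write("\t".join(["" , *matrix.col_labels]) + "\n")
        for label, row in zip(matrix.row_labels, matrix.values):
            cells = "\t".join(FLOAT_FMT % v for v in row)
            fh.write(f"{label}\t{cells}\n")


def write_enrichment(table: "pd.DataFrame", path: str | Path) -> None:
    """Write an enrichment table (term_id, name, k, K, n, N, p, p_adj, significant)."""
    out = table.copy()
    for col in ("p", "p_adj"):
        out[col] = out[col].map(lambda v: FLOAT_FMT % v)
    out.to_csv(path, sep="\t", index=False)


def write_network(
    edges: Iterable[tuple[str, str, float]],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write a weighted edge list as 3-column TSV or Cytoscape SIF.

    SIF rows read ``source<tab>sim<tab>target`` and drop the weight; an
    empty edge set yields a header-only TSV (or an empty SIF) without error.
    """
    path = Path(path)
    edges = list(edges)
    with path.open("w") as fh:
        if format == "tsv":
            fh.write("source\ttarget\tweight\n")
            for s, t, w in edges:
                fh.write(f"{s}\t{t}\t{FLOAT_FMT % w}\n")
        elif format == "sif":
            for s, t, _ in edges:
                fh.write(f"{s}\tsim\t{t}\n")
        else:
            raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "tsv") -> list[tuple[str, str]]:
    """Read an edge list written by :func:`write_network` (weights dropped)."""
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines()):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if format == "tsv":
            if lineno == 0 and fields[:2] == ["source", "target"]:
                continue
            pairs.append((fields[0], fields[1]))
        elif format == "sif":
            pairs.append((fields[0], fields[2]))
        else:
            raise ValueError(f"unknown network format {format!r}")
    return pairs
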