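"""Term-enrichment analysis for an entity set.

For each candidate term ``t`` (every non-root term in the propagated
annotation of at least one query member) a one-sided over-representation
test is run on the 2×2 table

    k out of the n annotated query members carry t,
    K out of the N background entities carry t,

with Fisher's exact test (upper-tail hypergeometric) or its binomial
approximation at rate ``K/N``.  Raw p-values are corrected for the number
of candidate terms with Bonferroni or Benjamini–Hochberg; a term is
flagged significant when the adjusted p-value is at or below ``alpha``
(default 0.05).
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError
from .ontology import AnnotationCorpus, OntologyGraph

log = logging.getLogger(__name__)

TESTS = ("fisher", "binomial")
CORRECTIONS = ("bonferroni", "bh")


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n)."""
    _check_counts(k, K, n, N)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"background rate must be in [0,1], got {p0}")
    return float(stats.binom.sf(k - 1, n, p0))


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent contingency counts k={k}, K={K}, n={n}, N={N}"
        )


def adjust(pvalues: list[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment, returned in input order and capped at 1.

    ``bonferroni`` multiplies by the family size m; ``bh`` is the
    Benjamini–Hochberg step-up: sort ascending and take
    ``min_{j >= i} m·p_(j)/j``.
    """
    if method not in CORRECTIONS:
        raise ValueError(f"unknown correction {method!r}; choose from {CORRECTIONS}")
    if len(pvalues) == 0:
        return []
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return list(multipletests(pvalues, method=key)[1])


def enrich(
    entity_set: list[str],
    corpus: AnnotationCorpus,
    graph: OntologyGraph,
    test: str = "fisher",
    correction: str = "bh",
    alpha: float = 0.05,
    namespace: str | None = None,
    background: list[str] | None = None,
) -> pd.DataFrame:
    """Enrichment table for a query entity set against a background.

    The background defaults to every annotated entity in the namespace; a
    custom background list restricts it.  Rows are sorted by adjusted
    p-value, ties by term id.  Unknown query entities are dropped with a
    warning; a query with no annotated member is an error.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if namespace is None:
        if len(graph.roots) != 1:
            raise EmptyInputError(
                f"ontology has namespaces {sorted(graph.roots)}; pick one"
            )
        namespace = next(iter(graph.roots))
    root = graph.root_of(namespace)

    bg = corpus.annotated_entities(namespace)
    if background is not None:
        bg &= set(background)
    members = []
    for e in dict.fromkeys(entity_set):  # dedupe, keep order
        if e in bg:
            members.append(e)
        else:
            log.warning("enrich: dropping entity %r (not in annotated background)", e)
    if not members:
        raise EmptyInputError("no query entity is annotated in the background")

    member_sets = {e: corpus.propagated_terms(e, namespace) for e in members}
    candidates = sorted(set().union(*member_sets.values()) - {root})
    n, N = len(members), len(bg)

    rows = []
    for t in candidates:
        k = sum(1 for e in members if t in member_sets[e])
        K = sum(1 for e in bg if t in corpus.propagated_terms(e, namespace))
        if test == "fisher":
            p = fisher_pvalue(k, K, n, N)
        else:
            p = binomial_pvalue(k, n, K / N)
        rows.append((t, graph.terms[t].name, k, K, n, N, p))

    table = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p"]
    )
    table["p_adj"] = adjust(list(table["p"]), correction)
    table["significant"] = table["p_adj"] <= alpha
    table = table.sort_values(
        ["p_adj", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table
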