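# Methods

## Ontology model

An ontology is modelled as a directed acyclic graph of terms with typed
child→parent edges. Only the subsumption relations `is_a` and `part_of`
are traversal edges — they drive ancestor closure, depth, information
content and every similarity measure; all other relationship types
(`regulates`, `develops_from`, ...) are parsed and retained but inert,
because the widely used biomedical ontologies express subsumption through
those two relations. Each namespace (GO's three sub-ontologies, for
example) must have exactly one parentless root, and cross-namespace
operations are rejected rather than silently scored zero.

Validation at parse time: every `[Term]` stanza must carry an `id`
(reported with its line number), the subsumption graph must be acyclic (a
cycle aborts parsing and names one member), and obsolete terms are
excluded from the graph while their ids remain resolvable — to a
`replaced_by` target when one is given, otherwise to nothing, in which
case annotations to them are dropped with a warning count. Flat-file
tokenisation is delegated to `obonet`; the validation layer is this
package's.

## Annotation corpus and information content

Annotations propagate by the true-path rule: each entity's propagated set
is the inclusive ancestor closure of its direct terms. The annotation
probability of a term is estimated as

    p(t) = n_t / n_root

where `n_t` counts **distinct entities** whose propagated set contains
`t` (never a sum over children — under multiple inheritance an entity
reachable through two parents is still one entity), and
`IC(t) = -ln p(t)` in nats. The natural log is used throughout; the
measures built on IC ratios (Lin, Rel, JC, simGIC) are base-invariant,
and nats are the convention elsewhere. Terms never annotated in the
corpus have *undefined* IC: measures touching one raise an error rather
than assuming 0 or ∞, because silent infinities corrupt exported
matrices.

Evidence codes are an optional third column; an evidence filter keeps
records whose code is in the filter *and* all records that carry no code
at all, since evidence is an attribute of an annotation rather than a
requirement. Duplicate records are collapsed silently.

## Between-term measures

Common ancestors are computed from *inclusive* ancestor sets, so
`mica(t, t) = t` and self-similarity is well defined (this is what makes
`Lin(t,t) = 1` hold). MICA ties on IC break to the lexicographically
smallest id for reproducible exports.

Degenerate-case conventions, applied consistently to Lin and its GraSM
variant: when `IC(t1) + IC(t2) = 0` (both terms as general as the root)
the similarity is defined as 1 for an identical pair and 0 otherwise —
the spec-level convention `Lin(root, root) = 1` generalised to any
IC-zero pair, since a 0/0 ratio carries no information either way.
`Wu2005(root, root)` is likewise defined as 1.

The Jiang–Conrath distance `d = IC(t1) + IC(t2) - 2·IC(MICA)` is mapped
to a similarity by `1/(1 + d)`: bounded, monotone, and the transform GO
toolkits conventionally use.

GraSM replaces `IC(MICA)` by the arithmetic mean IC over the disjoint
common ancestors — the common ancestors that are strict ancestors of no
other common ancestor, i.e. the most specific ones. For the relevance
measure the MICA probability is replaced by `exp(-share)`; since
`p(t) = exp(-IC(t))`, every GraSM variant (including Rel) collapses
exactly onto its base measure whenever the single DCA is the MICA — a
property the test suite exercises on random DAGs.

Edge-based formulas: Wu2005 uses the deepest common ancestor `a` (ties:
smaller summed path length, then lexicographic) and scores
`2·depth(a) / (len(t1→a) + len(t2→a) + 2·depth(a))`; Yu2005 scores
`1/(1 + d)` with `d` the shortest path between the terms through any
common ancestor. Both use shortest *directed* path lengths along
traversal edges.

Wang2007 S-values follow the standard recursion: `S_t(t) = 1`, and each
ancestor takes the maximum weighted contribution over its children
inside the term's inclusive-ancestor subgraph, with contribution factors
0.8 (`is_a`) and 0.6 (`part_of`) by default — the measure's published
defaults — and user-overridable per relation. A relation without a
configured factor is an error, not a silent zero.

Resnik is reported raw (in nats); an optional flag rescales by the
namespace's maximum IC when a [0, 1] range is needed for thresholding.

## Between-entity measures

Pairwise modes build the `|T1|×|T2|` term similarity matrix from the two
entities' **direct** term sets and combine it with Avg, Max, BMA
(`(Σ_i max_j + Σ_j max_i)/(n+m)`) or rcMax (`max` of row-best and
column-best means). Groupwise graph-based measures (TO, NTO, UI, LP,
simGIC) operate on the **extended** (propagated) sets — an annotation to
a term is implicitly an annotation to its ancestors. Vector-based
measures (cosine, kappa) default to binary vectors of **direct** terms
over the corpus term universe: a whole-ontology universe would make
kappa's chance agreement degenerate for any realistically sized
ontology. Both views can be overridden per call.

TO and LP are reported raw (a count and a depth); min-max rescaling is
available before network thresholding so that `[min, max]` windows stay
meaningful across measures. Kappa's degenerate case (chance agreement
exactly 1, i.e. both vectors constant) is scored 1 for identical sets
and 0 otherwise.

## Enrichment

Candidate terms are exactly those appearing in the propagated annotation
of at least one query member, excluding the namespace root (for which
k = n always — an always-significant artifact). The correction family
size is the number of candidates, not the ontology size. Both tests are
one-sided for over-representation: enrichment asks about significant
overlap, not depletion. The background defaults to every annotated
entity in the namespace and can be restricted by a user list. Fisher's
exact p-value is the upper hypergeometric tail via `scipy`; the binomial
test uses rate K/N with the query included in the background (excluding
it is a negligible correction at corpus scale). Bonferroni and
Benjamini–Hochberg go through `statsmodels.multipletests`; the test
suite verifies BH against an independently coded step-up formula.

## Networks

Similarity networks keep unordered pairs whose score lies in the closed
window `[min, max]` — inclusive at both ends, as the Min/Max naming
implies — ignoring the diagonal; edges are stored with lexicographically
sorted endpoints and emitted in sorted order. Imported edge lists are
re-weighted edge-for-edge (never inventing edges); self-loops are
dropped with a warning, and an edge with an unannotated endpoint is
either dropped (default) or kept at weight 0. Set-vs-set similarity
combines the cross-set entity matrix with BMA by default — the balanced
choice among the pairwise combiners — with the others available.

## Synthetic data

All tests run on generated fixtures, not ontology snapshots. The DAG
generator adds terms in topological order, giving each non-root term 1 to
`max_parents` parents among earlier terms (acyclic and single-rooted by
construction), with each parent edge `part_of` with probability
`part_of_fraction` (default 0.2, is_a-dominant like real ontologies);
entities draw 1–3 annotation terms uniformly among non-root terms.
Defaults (20 terms, 10 entities, 2 max parents) keep per-fixture work
trivial while still producing multiple inheritance, diamonds and
multi-DCA pairs; property suites run hundreds of seeds. One seeded
generator stream per spec makes outputs byte-reproducible.

What the generator does *not* emulate: the power-law branching and depth
profile of real ontologies, annotation bias toward shallow terms,
correlated annotations between related entities, and evidence-code
distributions. Passing property tests therefore demonstrates
correctness of the algorithms on arbitrary DAG shapes, not calibration
of any measure's score distribution on GO- or HPO-scale data.

## Numerical choices

Probabilities and ICs are exact ratios of small integers in double
precision; no smoothing or pseudo-counts are applied. All iteration
orders that reach an output file are fixed by sorting, and floats are
written with 6 decimal places, so identical invocations produce
byte-identical files. Tolerances in tests are 1e-6 absolute for
hand-derived values and 1e-9 relative against enumeration oracles.

## Known limitations

Single-threaded; Wang2007 recomputes S-values per pair, which is the
right trade-off at interactive scale but quadratic-cost for
whole-corpus matrices. OWL/RDF inputs, GAF/GPAD annotation dialects,
intrinsic (corpus-free) IC variants and topology-aware enrichment
(elim/weight) are out of scope.
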