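# Methods

## The credibility model

Every row of a gene list or gene-pair list carries evidence items (source,
raw score, score kind, acquisition date) and a credibility state. User
credibilities live in the open interval (−1, 1); the default for every
source and score is 0.5. The mapping onto Dempster–Shafer mass functions
puts positive credibility on {T}, negative credibility on {F}, and the
remainder on the uncertain set {T, F}; this is the only assignment
consistent with 0 meaning total uncertainty and the two signs meaning
belief and disbelief. The empty set never carries mass: total conflict
(perfect belief combined with perfect disbelief, K⁻¹ = 0) is raised as an
error rather than silently renormalised, because with the open credibility
interval it can only arise from programmatic mass functions, and surfacing
it is safer than hiding it.

A row's combined credibility is Bel({T}) — not plausibility — of the
orthogonal-sum fold over one mass per evidence source (looked up in the
source registry), one for the score credibility, and one for the
size-of-group credibility when the row belongs to an enrichment group.
Because the orthogonal sum is commutative and associative, the fold order
is irrelevant; combining n agreeing credibilities of 0.5 yields 1 − 0.5ⁿ,
which is the calibration anchor the tests check in closed form.

Score normalisation maps every score kind onto a nonnegative
"bigger-is-more-significant" axis: −log₁₀ for p-values (p = 0 is floored at
1e−300 with a warning so the logarithm stays finite), identity for article
counts and percent identities, absolute value for net expression
direction. Partitioning of the normalised axis fits 1-D Gaussian mixtures
by EM for k = 1..6 and selects k by BIC; boundaries sit at midpoints
between adjacent component means and every new interval starts at
credibility 0.5. A score equal to a boundary belongs to the right-hand
interval. Adding or removing a single divider re-clusters the scores into
k ± 1 contiguous groups by an exact dynamic program minimising within-group
sum of squares (deterministic, no seeding required); surviving intervals
inherit credibilities by nearest interval midpoint. Group sizes can be run
through the same partition machinery (`assign_group_credibility`), or
graded per group by hand.

Source learning applies one of five rates (+0.030, +0.015, 0, −0.015,
−0.030) per feedback event, ordered from strongest agreement to strongest
disagreement with the neutral middle fixed at zero, clamping the credibility
strictly inside (−1, 1) so repeated feedback converges toward, but never
reaches, perfect (dis)belief.

## Enrichment statistics

Term enrichment uses the upper-tail hypergeometric probability. The
annotation map is closed upward under the true-path rule before testing, so
|ann(parent)| ≥ |ann(child)| along every is_a edge. Term-for-term draws
from the whole population (unannotated genes count in N but in no K); the
parent-child variants condition on pa∪(t) (genes annotated to any parent)
or pa∩(t) (genes annotated to every parent), testing k = |study ∩ ann(t)|
successes in n = |study ∩ pa(t)| draws from N = |pa(t)| with K = |ann(t)|.
Root terms have no conditioning set and are excluded. The disease-term
variant runs the union strategy unchanged on the disease hierarchy. No
multiple-testing correction is applied — raw p-values feed the credibility
engine — but a Bonferroni column is emitted in CSV exports for information.

Expression scoring is n_up − n_down per (gene, condition); the list-level
statistic is an exact two-sided sign test (binomial, p₀ = ½) over genes
with nonzero net direction, the minimal test consistent with a pure
direction score. One result is emitted per condition for the dominant
direction's gene group.

Chromosomal proximity clusters study genes per chromosome by single linkage
on start positions with a gap threshold (default 1 Mb, configurable). For
each cluster of k ≥ 2 genes with span s, the p-value is the add-one
Monte-Carlo estimate ((r+1)/(n_perm+1), default 10,000 seeded draws) of the
probability that k genes sampled uniformly without replacement from the
chromosome's gene complement span ≤ s. Spans depend only on position
differences, so p-values are invariant under a global coordinate shift. An
exact combinatorial order-statistic computation over the actual position
set (counting qualifying k-subsets by their leftmost member) serves as the
independent check. Coordinates are 0-based half-open internally; 1-based
gene TSVs are converted on read, BED taken as-is; strand is ignored since
only start positions enter the statistic.

Pair-list enrichment runs the chosen single-gene enricher on the union of
the two columns' genes; a pair belongs to a term's group iff both its genes
do, and inherits the group p-value.

## List algebra and the interolog pipeline

Union/intersect/difference act on key sets (gene id; ordered id pair for
pair lists, with an undirected option for symmetric interactions).
Evidence from coinciding rows concatenates, deduplicated by source with the
more significant score kept — mirroring the query-merge precedence rule in
which a focused source's p-value beats a general source's 0.05 default.
Translate joins A–B with B–C on the shared middle gene; each output pair's
belief is the Dempster combination of the supporting rows' combined
beliefs, folded over all supporting paths, which keeps belief propagation
uniform across single queries and multi-hop chains.

The interolog pipeline composes these primitives per via species
(orthologs out → via interactions → translate → orthologs back →
translate), pools candidates over via species by union (a pair found
through two species carries both evidence chains, Dempster-combined), and
subtracts the query species' known interactions, matching either
orientation by default. The pipeline asserts on every run that no
prediction coincides with a known pair.

## Synthetic data

The generator emulates all input formats with planted structure: an
11-term, 4-level ontology in which one two-parent leaf term is annotated to
80% of a 10-gene study set (plus two background genes) inside a 60-gene
population, with both parents sharing a 15-gene direct-annotation pool so
the parent-child conditioning sets properly exceed the planted term; a
5-gene cluster spanning ≤ 200 kb among 1,000 uniformly placed genes on a
20 Mb chromosome, plus a second chromosome with deliberately scattered
study genes; one expression condition skewed upward for the study set;
term-to-gene tables with overlapping focused/general coverage; and an
ortholog/interaction triangle modelled on the fly/human MED26 case — the
human gene IDs are real (9441, 29079, 10025, 9440), the fly partner IDs
synthetic — including one already-known fly edge so the final difference
has something to remove. Background interaction density is kept low
(expected degree well under 3) so the planted signal dominates at fixture
scale. A manifest records every planted truth; identical seeds reproduce
byte-identical files.

What the fixtures do not emulate: genome-scale data volumes, realistic
annotation depth or degree distributions, identifier synonymy, or noisy /
contradictory sources. Passing tests therefore demonstrate correctness of
the statistics and plumbing on controlled inputs, not recovery power on
real databases.

## Numerical and design choices

- Hypergeometric tails come from `scipy.stats.hypergeom.sf`; exhaustive
  enumeration oracles bound populations at 12 where exact comparison is
  feasible.
- Mass functions validate nonnegativity and unit sum to 1e−9; oracle
  agreement is asserted to 1e−12 and associativity to 1e−10.
- Sorting of list rows is a stable sort on the requested key only, so rows
  with equal keys keep their original relative order.
- Duplicate genes within one import collapse to a single entry with merged
  evidence; lists are sets.
- Pair columns carry independent species so cross-species ortholog lists
  are first-class; difference over interaction lists defaults to ordered
  keys with an explicit undirected flag (used by the interolog pipeline).
- Enrichment population defaults to the whole annotated genome of the
  list's species (overridable); genes missing coordinates or expression
  rows are reported and skipped rather than failing the run.
- The workflow XML schema is this package's own, versioned (`schema="1.0"`),
  with node names normalised to sorted order so save→load→save is
  byte-stable; loading refuses unknown schema versions and dangling edges.
- Test problem sizes (60-gene population, 1,000-gene chromosome, 10,000
  permutations, 20 generator seeds) were chosen as the smallest scales at
  which every planted structure is unambiguous and exact oracles remain
  cheap to enumerate.

## Known limitations

- Only is_a edges are honoured in ontologies; part_of and other
  relationships are dropped with a count warning.
- Symbol resolution is exact-match against a user-supplied map; no synonym
  service is emulated.
- The proximity null is uniform sampling of gene starts within a
  chromosome; it does not model gene-density heterogeneity.
- Source credibilities are global per source, not per (source, species) or
  per query type.
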