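"""Term, expression and positional enrichment over gene and gene-pair lists.

Term enrichment supports the classic term-for-term hypergeometric test and
the two parent-child strategies, which condition each term's test on the
genes annotated to its parents (union or intersection of the parent
annotation sets) rather than on the whole population — reducing the cascade
of trivially "enriched" ancestors that term-for-term produces on a DAG.
The same machinery runs on a disease-term hierarchy.  Expression enrichment
scores each gene by net direction (up-experiments minus down-experiments)
and tests the directional skew of a list with an exact sign test.
Chromosomal-proximity enrichment finds clusters of study genes and asks how
often an equally tight cluster arises by chance on the same chromosome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .model import CredibilityState, DEFAULT_CREDIBILITY
from . import belief

__all__ = [
    "EnrichmentResult",
    "TermGraph",
    "cap_results",
    "expression_enrichment",
    "expression_score",
    "exact_span_probability",
    "filter_evidence",
    "mesh_enrichment",
    "pair_enrichment",
    "parent_child_intersection",
    "parent_child_union",
    "proximity_enrichment",
    "term_for_term",
]

#: GO evidence code for computational-only annotations
IEA = "IEA"


@dataclass
class TermGraph:
    """A DAG of terms plus term -> gene annotation sets.

    Edges run child -> parent (more specific -> more general).  After
    loading, annotation sets are closed upward under the true-path rule: a
    gene annotated to a term is annotated to every ancestor of that term,
    so ``|ann(parent)| >= |ann(child)|`` along every edge.
    """

    graph: nx.DiGraph
    annotations: dict[str, set[int]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    #: raw (gene, term, evidence_code) records before closure
    raw_annotations: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cyc = nx.find_cycle(self.graph)
            raise ValueError(f"term graph contains a cycle through {cyc[0][0]!r}")

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def roots(self) -> set[str]:
        return {t for t in self.graph if self.graph.out_degree(t) == 0}

    def ann(self, term: str) -> set[int]:
        return self.annotations.get(term, set())

    def attach_annotations(
        self, records: Iterable[tuple[int, str, str]]
    ) -> "TermGraph":
        """Attach raw annotation records and apply true-path closure.

        Records annotating terms absent from the graph are dropped with a
        warning.  Returns self.
        """
        self.raw_annotations = []
        dropped = 0
        for gene, term, code in records:
            if term not in self.graph:
                dropped += 1
                continue
            self.raw_annotations.append((int(gene), term, code))
        if dropped:
            warnings.warn(
                f"{dropped} annotation rows referenced unknown terms and were dropped",
                RuntimeWarning,
                stacklevel=2,
            )
        self._close()
        return self

    def _close(self, exclude_codes: frozenset[str] = frozenset()) -> None:
        direct: dict[str, set[int]] = {t: set() for t in self.graph}
        for gene, term, code in self.raw_annotations:
            if code in exclude_codes:
                continue
            direct[term].add(gene)
        ann = {t: set(direct[t]) for t in self.graph}
        # children precede parents in topological order of child->parent edges
        for t in nx.topological_sort(self.graph):
            for child in self.graph.predecessors(t):
                ann[t] |= ann[child]
        self.annotations = ann

    def annotated_genes(self) -> set[int]:
        out: set[int] = set()
        for s in self.annotations.values():
            out |= s
        return out


def filter_evidence(graph: TermGraph, mode: str) -> TermGraph:
    """Restrict annotations by evidence code before true-path closure.

    ``curated_only`` removes IEA (computational-only) annotations;
    ``all_types`` is the identity.
    """
    if mode not in ("curated_only", "all_types"):
        raise ValueError(f"unknown evidence mode {mode!r}")
    if mode == "all_types":
        return graph
    out = TermGraph(graph.graph, names=dict(graph.names))
    out.raw_annotations = [r for r in graph.raw_annotations if r[2] != IEA]
    out._close()
    return out


@dataclass
class EnrichmentResult:
    """One enriched group: the term, its member rows, and the p-value."""

    term: str
    name: str
    member_genes: set
    p_value: float
    group_size: int = 0
    credibility: CredibilityState = field(default_factory=CredibilityState)

    def __post_init__(self) -> None:
        if self.group_size == 0:
            self.group_size = len(self.member_genes)
        if not 0.0 < self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value!r} outside (0, 1]")
        self.p_value = min(self.p_value, 1.0)
        if self.credibility.combined == 0.0:
            # default belief: neutral source mass + neutral score mass
            self.credibility.combined = belief.combined_credibility(
                [DEFAULT_CREDIBILITY, DEFAULT_CREDIBILITY]
            )


def _ids(genes) -> set[int]:
    if hasattr(genes, "gene_ids"):
        return genes.gene_ids()
    return {int(g) if isinstance(g, (int, np.integer)) else g.id for g in genes}


def _upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def term_for_term(study, population, graph: TermGraph) -> list[EnrichmentResult]:
    """Classic hypergeometric over-representation of each term.

    For each term with at least one study annotation, the p-value is the
    upper tail of drawing ``k`` study genes annotated to the term out of
    ``n = |study|`` draws from a population of ``N`` containing ``K``
    annotated genes.  Unannotated population genes count in N but in no K.
    """
    study_ids, pop_ids = _ids(study), _ids(population)
    if not study_ids <= pop_ids:
        raise ValueError(
            f"study set is not a subset of the population "
            f"(offending genes: {sorted(study_ids - pop_ids)[:5]})"
        )
    N, n = len(pop_ids), len(study_ids)
    out = []
    for term in sorted(graph.graph):
        ann = graph.ann(term) & pop_ids
        members = study_ids & ann
        if not members:
            continue
        p = _upper_tail(len(members), N, len(ann), n)
        out.append(
            EnrichmentResult(term, graph.names.get(term, term), members, p)
        )
    return sorted(out, key=lambda r: (r.p_value, -r.group_size, r.term))


def _parent_child(
    study, population, graph: TermGraph, combine: str
) -> list[EnrichmentResult]:
    study_ids, pop_ids = _ids(study), _ids(population)
    if not study_ids <= pop_ids:
        raise ValueError("study set is not a subset of the population")
    out = []
    for term in sorted(graph.graph):
        parents = graph.parents(term)
        if not parents:  # root terms have no conditioning set
            continue
        sets = [graph.ann(p) & pop_ids for p in parents]
        if combine == "union":
            pa = set().union(*sets)
        else:
            pa = set.intersection(*sets)
        ann = graph.ann(term) & pop_ids
        if not ann <= pa:
            raise RuntimeError(
                f"annotations of {term!r} escape its parent set after "
                "true-path closure; the graph is inconsistent"
            )
        members = study_ids & ann
        if not members:
            continue
        N = len(pa)
        K = len(ann)
        n = len(study_ids & pa)
        k = len(members)
        if N == 0 or n == 0:
            continue
        p = _upper_tail(k, N, K, n)
        out.append(
            EnrichmentResult(term, graph.names.get(term, term), members, p)
        )
    return sorted(out, key=lambda r: (r.p_value, -r.group_size, r.term))


def parent_child_union(study, population, graph: TermGraph) -> list[EnrichmentResult]:
    """Parent-child enrichment conditioning on the union of parent sets.

    For term t the conditioning universe is pa∪(t) — genes annotated to any
    parent of t; the test asks whether the study hits on t are surprising
    given how much of the study lies in pa∪(t).
    """
    return _parent_child(study, population, graph, "union")


def parent_child_intersection(
    study, population, graph: TermGraph
) -> list[EnrichmentResult]:
    """Parent-child enrichment conditioning on the intersection of parent
    sets (genes annotated to every parent of t) — the stricter variant,
    returning at most as many enriched terms as the union strategy."""
    return _parent_child(study, population, graph, "intersection")


def mesh_enrichment(study, population, disease_graph: TermGraph) -> list[EnrichmentResult]:
    """Disease-term enrichment: parent-child union on the disease hierarchy."""
    return parent_child_union(study, population, disease_graph)


def cap_results(
    results: Sequence[EnrichmentResult], max_hits: int
) -> list[EnrichmentResult]:
    """Keep the ``max_hits`` most significant groups.

    Ties on p break toward the larger group, then lexicographic term id.
    """
    if max_hits < 1:
        raise ValueError("max_hits must be a positive integer")
    ranked = sorted(results, key=lambda r: (r.p_value, -r.group_size, r.term))
    return ranked[:max_hits]


def expression_score(gene_id: int, condition: str, table) -> int:
    """Net expression direction: up-experiments minus down-experiments.

    Positive means more evidence for up-regulation under the condition.
    Raises KeyError when the (gene, condition) row is absent.
    """
    df = table.df
    row = df[(df["gene"] == gene_id) & (df["condition"] == condition)]
    if row.empty:
        raise KeyError(f"no expression data for gene {gene_id} under {condition!r}")
    return int(row["n_up"].iloc[0] - row["n_down"].iloc[0])


def expression_enrichment(
    study, conditions: Iterable[str], table
) -> list[EnrichmentResult]:
    """Directional skew of a study set under each condition.

    Genes are grouped by the sign of their net expression score; the group
    p-value is an exact two-sided sign test (binomial, p0 = 1/2) over the
    genes with a nonzero score.  Genes without data are omitted; conditions
    with no data are skipped with a notice.
    """
    study_ids = sorted(_ids(study))
    out = []
    for cond in conditions:
        scores = {}
        for g in study_ids:
            try:
                scores[g] = expression_score(g, cond, table)
            except KeyError:
                continue
        if not scores:
            warnings.warn(
                f"condition {cond!r} has no data for any study gene; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        up = {g for g, s in scores.items() if s > 0}
        down = {g for g, s in scores.items() if s < 0}
        nonzero = len(up) + len(down)
        if nonzero == 0:
            p = 1.0
        else:
            p = float(stats.binomtest(len(up), nonzero, 0.5).pvalue)
        direction = "up" if len(up) >= len(down) else "down"
        members = up if direction == "up" else down
        if not members:
            continue
        res = EnrichmentResult(f"{cond}[{direction}]", f"{cond} ({direction})", members, p)
        # per-gene net scores ride along for downstream credibility work
        res.scores = {g: scores[g] for g in members}
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# chromosomal proximity


def _clusters(positions: dict[int, int], window_bp: int) -> list[list[int]]:
    """Single-linkage clusters of genes by start position (gap <= window)."""
    genes = sorted(positions, key=lambda g: (positions[g], g))
    clusters, current = [], [genes[0]]
    for g in genes[1:]:
        if positions[g] - positions[current[-1]] <= window_bp:
            current.append(g)
        else:
            clusters.append(current)
            current = [g]
    clusters.append(current)
    return clusters


def exact_span_probability(positions: Sequence[int], k: int, span: int) -> float:
    """Exact P(span of k genes drawn without replacement <= span).

    Combinatorial order-statistic computation over the actual position set:
    counting k-subsets by their leftmost member, a subset with minimum at
    x_i and span <= s chooses its other k-1 members from the points in
    (x_i, x_i + s].
    """
    xs = sorted(positions)
    n = len(xs)
    if k > n:
        return 1.0 if k <= 0 else 0.0
    total = math.comb(n, k)
    count = 0
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and xs[j + 1] - xs[i] <= span:
            j += 1
        within = j - i  # points after i within the window
        if within >= k - 1:
            count += math.comb(within, k - 1)
    return count / total


def proximity_enrichment(
    study,
    coords,
    *,
    window_bp: int = 1_000_000,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Chromosomal clustering of a study set against a positional null.

    Study genes on each chromosome are clustered by single linkage on start
    position (gap <= ``window_bp``).  For each cluster of k >= 2 genes with
    span s, the p-value is the Monte-Carlo probability (``n_perm`` seeded
    draws, add-one rule) that k genes drawn uniformly without replacement
    from the chromosome's full gene complement span <= s.  Spans depend only
    on position differences, so the p-values are invariant under a global
    shift of all starts.  Study genes missing coordinates are reported in a
    warning and skipped.
    """
    df = coords.df
    pos = {int(r.gene): (r.chrom, int(r.start)) for r in df.itertuples()}
    study_ids = sorted(_ids(study))
    missing = [g for g in study_ids if g not in pos]
    if missing:
        warnings.warn(
            f"{len(missing)} study genes lack coordinates and were skipped: "
            f"{missing[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
    by_chrom: dict[str, dict[int, int]] = {}
    for g in study_ids:
        if g in pos:
            chrom, start = pos[g]
            by_chrom.setdefault(chrom, {})[g] = start
    pop_lists: dict[str, list[int]] = {}
    for g, (chrom, start) in pos.items():
        pop_lists.setdefault(chrom, []).append(start)
    pop_by_chrom = {c: np.asarray(sorted(v)) for c, v in pop_lists.items()}

    rng = np.random.default_rng(seed)
    out = []
    for chrom in sorted(by_chrom):
        for cluster in _clusters(by_chrom[chrom], window_bp):
            if len(cluster) < 2:
                continue
            k = len(cluster)
            starts = [by_chrom[chrom][g] for g in cluster]
            span = max(starts) - min(starts)
            popn = pop_by_chrom[chrom]
            if len(popn) <= k:
                p = 1.0
            else:
                hits = 0
                batch = 2000
                done = 0
                while done < n_perm:
                    b = min(batch, n_perm - done)
                    u = rng.random((b, len(popn)))
                    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
                    sel = popn[idx]
                    spans = sel.max(axis=1) - sel.min(axis=1)
                    hits += int(np.sum(spans <= span))
                    done += b
                p = (hits + 1) / (n_perm + 1)
            term = f"{chrom}:{min(starts)}-{max(starts)}"
            out.append(
                EnrichmentResult(term, f"cluster on {chrom}", set(cluster), p)
            )
    return sorted(out, key=lambda r: (r.p_value, -r.group_size, r.term))


def pair_enrichment(
    pairs, enricher: Callable, *args, **kwargs
) -> list[EnrichmentResult]:
    """Run a single-gene enrichment over a pair list.

    The enricher runs on the union of the two columns' genes; a pair is a
    member of a term's group iff *both* of its genes are, and it inherits
    the group's p-value as its score.
    """
    union_ids = {e.input_gene.id for e in pairs} | {e.output_gene.id for e in pairs}
    base = enricher(union_ids, *args, **kwargs)
    out = []
    for res in base:
        members = {
            e.key
            for e in pairs
            if e.input_gene.id in res.member_genes
            and e.output_gene.id in res.member_genes
        }
        if not members:
            continue
        out.append(EnrichmentResult(res.term, res.name, members, res.p_value))
    return out
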