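"""Enrichment statistics against exhaustive-enumeration oracles."""

import itertools
import math
import warnings

import networkx as nx
import numpy as np
import pytest

from credence import enrichment
from credence.enrichment import (
    EnrichmentResult,
    TermGraph,
    cap_results,
    exact_span_probability,
    expression_enrichment,
    expression_score,
    filter_evidence,
    pair_enrichment,
    parent_child_intersection,
    parent_child_union,
    proximity_enrichment,
    term_for_term,
)

import credence.io as data_io
from credence.model import EvidenceItem, Gene, GenePairEntry, GenePairList, Provenance
import datetime

TODAY = datetime.date(2010, 12, 30)


def enumeration_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    pop = list(range(N))
    annotated = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(pop, n) if len(annotated & set(draw)) >= k
    )
    return hits / math.comb(N, n)


def build_graph(edges, annotations):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    tg = TermGraph(g)
    tg.attach_annotations(annotations)
    return tg


class TestTermForTerm:
    def test_all_study_annotated_equals_enumeration(self):
        # N=10, K=5, n=5, k=5: p = 1/C(10,5) = 1/252
        tg = build_graph(
            [("t", "root")], [(g, "t", "EXP") for g in range(5)]
        )
        res = term_for_term(set(range(5)), set(range(10)), tg)
        hit = [r for r in res if r.term == "t"][0]
        assert hit.p_value == pytest.approx(1 / 252, abs=1e-12)
        assert hit.p_value == pytest.approx(enumeration_tail(10, 5, 5, 5), abs=1e-12)

    def test_matches_enumeration_for_small_populations(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(4, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            tg = build_graph(
                [("t", "root")], [(g, "t", "EXP") for g in range(K)]
            )
            study = set(rng.choice(N, size=n, replace=False).tolist())
            k = len(study & set(range(K)))
            if k == 0:
                continue
            res = {r.term: r for r in term_for_term(study, set(range(N)), tg)}
            assert res["t"].p_value == pytest.approx(
                enumeration_tail(N, K, n, k), abs=1e-12
            )

    def test_whole_population_term_has_p_one(self):
        tg = build_graph([("t", "root")], [(g, "t", "EXP") for g in range(8)])
        res = {r.term: r for r in term_for_term(set(range(3)), set(range(8)), tg)}
        assert res["t"].p_value == pytest.approx(1.0)

    def test_terms_without_study_hits_omitted(self):
        tg = build_graph(
            [("t", "root"), ("u", "root")],
            [(1, "t", "EXP"), (9, "u", "EXP")],
        )
        res = term_for_term({1}, {1, 9, 10}, tg)
        assert {r.term for r in res} == {"t", "root"}

    def test_study_outside_population_rejected(self):
        tg = build_graph([("t", "root")], [(1, "t", "EXP")])
        with pytest.raises(ValueError):
            term_for_term({1, 99}, {1, 2}, tg)


class TestParentChild:
    def toy(self):
        # 8 genes, 4 terms: t under both a and b, which hang off root
        edges = [("a", "root"), ("b", "root"), ("t", "a"), ("t", "b")]
        ann = (
            [(g, "t", "EXP") for g in (0, 1, 2)]
            + [(g, "a", "EXP") for g in (3, 4, 5)]
            + [(g, "b", "EXP") for g in (4, 5, 6)]
        )
        return build_graph(edges, ann)

    def test_union_matches_enumeration_oracle(self):
        tg = self.toy()
        study = {0, 1, 4}
        pop = set(range(8))
        res = {r.term: r for r in parent_child_union(study, pop, tg)}
        pa = tg.ann("a") | tg.ann("b")
        annt = tg.ann("t")
        n = len(study & pa)
        k = len(study & annt)
        # enumeration over draws from the conditioning set pa
        pa_list = sorted(pa)
        hits = sum(
            1
            for draw in itertools.combinations(pa_list, n)
            if len(annt & set(draw)) >= k
        )
        expected = hits / math.comb(len(pa), n)
        assert res["t"].p_value == pytest.approx(expected, abs=1e-12)

    def test_intersection_matches_enumeration_oracle(self):
        tg = self.toy()
        study = {0, 1, 4}
        pop = set(range(8))
        res = {r.term: r for r in parent_child_intersection(study, pop, tg)}
        pa = tg.ann("a") & tg.ann("b")
        annt = tg.ann("t")
        n = len(study & pa)
        k = len(study & annt)
        hits = sum(
            1
            for draw in itertools.combinations(sorted(pa), n)
            if len(annt & set(draw)) >= k
        )
        expected = hits / math.comb(len(pa), n)
        assert res["t"].p_value == pytest.approx(expected, abs=1e-12)

    def test_child_identical_to_parent_gives_p_one(self):
        tg = build_graph(
            [("t", "a"), ("a", "root")], [(g, "t", "EXP") for g in range(4)]
        )
        res = {r.term: r for r in parent_child_union({0, 1}, set(range(6)), tg)}
        assert res["t"].p_value == pytest.approx(1.0)

    def test_single_parent_union_equals_intersection(self):
        tg = build_graph(
            [("t", "a"), ("a", "root")],
            [(g, "t", "EXP") for g in range(3)] + [(g, "a", "EXP") for g in (3, 4)],
        )
        study = {0, 1}
        pop = set(range(6))
        u = {r.term: r.p_value for r in parent_child_union(study, pop, tg)}
        i = {r.term: r.p_value for r in parent_child_intersection(study, pop, tg)}
        assert u == pytest.approx(i)

    def test_root_terms_excluded(self):
        tg = self.toy()
        res = parent_child_union({0, 1}, set(range(8)), tg)
        assert all(r.term != "root" for r in res)

    def test_intersection_never_returns_more_terms(self, term_graph, manifest):
        study = set(manifest["study_genes"])
        pop = set(manifest["population"])
        for cutoff in (0.001, 0.01, 0.05, 0.5):
            nu = sum(
                r.p_value <= cutoff
                for r in parent_child_union(study, pop, term_graph)
            )
            ni = sum(
                r.p_value <= cutoff
                for r in parent_child_intersection(study, pop, term_graph)
            )
            assert ni <= nu

    def test_planted_term_ranks_first_in_all_methods(self, term_graph, manifest):
        study = set(manifest["study_genes"])
        pop = set(manifest["population"])
        planted = manifest["planted_term"]
        ancestors = nx.descendants(term_graph.graph, planted)
        for fn in (
            term_for_term,
            parent_child_union,
            parent_child_intersection,
            enrichment.mesh_enrichment,
        ):
            res = [r for r in fn(study, pop, term_graph) if r.term not in ancestors]
            assert res[0].term == planted, fn.__name__


class TestClosureAndFiltering:
    def test_true_path_rule_makes_parents_superset(self, term_graph):
        for child, parent in term_graph.graph.edges:
            assert term_graph.ann(child) <= term_graph.ann(parent)

    def test_curated_only_drops_iea_before_closure(self):
        tg = build_graph(
            [("t", "root")],
            [(1, "t", "IEA"), (2, "t", "EXP"), (3, "root", "IEA")],
        )
        cur = filter_evidence(tg, "curated_only")
        assert cur.ann("t") == {2}
        assert cur.ann("root") == {2}
        assert filter_evidence(tg, "all_types") is tg

    def test_all_iea_yields_empty_annotations(self):
        tg = build_graph([("t", "root")], [(1, "t", "IEA")])
        cur = filter_evidence(tg, "curated_only")
        assert cur.ann("t") == set() and cur.ann("root") == set()

    def test_mixed_codes_count_matches_row_filter(self, fixture_dir, term_graph):
        rows = [r for r in term_graph.raw_annotations if r[2] != "IEA"]
        cur = filter_evidence(term_graph, "curated_only")
        assert len(cur.raw_annotations) == len(rows)

    def test_cycle_rejected(self):
        g = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="cycle"):
            TermGraph(g)


class TestCapResults:
    def mk(self, term, p, size):
        return EnrichmentResult(term, term, set(range(size)), p)

    def test_keeps_smallest_p(self):
        res = cap_results([self.mk("a", 0.2, 2), self.mk("b", 0.01, 2)], 1)
        assert [r.term for r in res] == ["b"]

    def test_identity_when_max_exceeds(self):
        rs = [self.mk("a", 0.2, 2), self.mk("b", 0.01, 2)]
        assert len(cap_results(rs, 10)) == 2

    def test_tie_on_p_prefers_larger_group(self):
        res = cap_results([self.mk("a", 0.05, 2), self.mk("b", 0.05, 5)], 1)
        assert res[0].term == "b"


class TestExpression:
    @pytest.fixture()
    def table(self, fixture_dir):
        return data_io.read_expression(fixture_dir / "expression.tsv")

    def test_net_score_arithmetic(self, table, manifest):
        import pandas as pd

        g = manifest["study_genes"][0]
        cond = manifest["expression_condition"]
        df = table.df
        row = df[(df["gene"] == g) & (df["condition"] == cond)].iloc[0]
        assert expression_score(g, cond, table) == row.n_up - row.n_down

    def test_missing_row_raises(self, table):
        with pytest.raises(KeyError):
            expression_score(999999, "hypoxia", table)

    def test_all_up_sign_test(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene": list(range(6)),
                "condition": ["c"] * 6,
                "n_up": [5] * 6,
                "n_down": [1] * 6,
            }
        )
        table = data_io.SourceTable("t", "expression", df, TODAY)
        res = expression_enrichment(set(range(6)), ["c"], table)
        assert res[0].p_value == pytest.approx(2 * 0.5**6)
        assert res[0].group_size == 6

    def test_balanced_gives_p_one(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene": list(range(6)),
                "condition": ["c"] * 6,
                "n_up": [3, 3, 3, 1, 1, 1],
                "n_down": [1, 1, 1, 3, 3, 3],
            }
        )
        table = data_io.SourceTable("t", "expression", df, TODAY)
        res = expression_enrichment(set(range(6)), ["c"], table)
        assert res[0].p_value == pytest.approx(1.0)

    def test_absent_condition_skipped_with_notice(self, table):
        with pytest.warns(RuntimeWarning):
            res = expression_enrichment({1001}, ["no-such-condition"], table)
        assert res == []


class TestProximity:
    def test_planted_cluster_significant_and_near_exact(
        self, coords_table, manifest
    ):
        planted = manifest["planted_cluster"]
        study = set(manifest["proximity_study_genes"])
        n_perm = 10_000
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = proximity_enrichment(
                study, coords_table, n_perm=n_perm, seed=11
            )
        top = res[0]
        assert top.member_genes == set(planted["genes"])
        assert top.p_value < 0.01
        chrom_positions = coords_table.df[
            coords_table.df["chrom"] == planted["chrom"]
        ]["start"].tolist()
        exact = exact_span_probability(
            chrom_positions, len(planted["genes"]), planted["span_bp"]
        )
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n_perm)
        assert abs(top.p_value - exact) <= 3 * se + 2 / n_perm

    def test_scattered_genes_form_no_cluster(self, coords_table):
        res = proximity_enrichment(
            {5001, 5002, 5003}, coords_table, n_perm=100, seed=1
        )
        assert res == []

    def test_whole_chromosome_cluster_has_p_one(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene": [1, 2, 3],
                "chrom": ["X"] * 3,
                "start": [100, 200, 300],
                "symbol": [""] * 3,
            }
        )
        table = data_io.SourceTable("c", "coordinates", df, TODAY)
        res = proximity_enrichment({1, 2, 3}, table, n_perm=100, seed=1)
        assert res[0].p_value == pytest.approx(1.0)

    def test_shift_invariance(self, coords_table, manifest):
        study = set(manifest["proximity_study_genes"])
        df = coords_table.df.copy()
        df["start"] = df["start"] + 5_000_000
        shifted = data_io.SourceTable("c", "coordinates", df, TODAY)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = proximity_enrichment(study, coords_table, n_perm=500, seed=5)
            b = proximity_enrichment(study, shifted, n_perm=500, seed=5)
        assert [r.p_value for r in a] == pytest.approx([r.p_value for r in b])

    def test_missing_coordinates_reported(self, coords_table, manifest):
        study = set(manifest["proximity_study_genes"]) | {987654}
        with pytest.warns(RuntimeWarning, match="987654"):
            proximity_enrichment(study, coords_table, n_perm=10, seed=1)

    def test_exact_span_probability_enumeration(self):
        rng = np.random.default_rng(8)
        pos = sorted(rng.choice(1000, size=9, replace=False).tolist())
        k, s = 3, 150
        brute = sum(
            1
            for sub in itertools.combinations(pos, k)
            if max(sub) - min(sub) <= s
        ) / math.comb(len(pos), k)
        assert exact_span_probability(pos, k, s) == pytest.approx(brute, abs=1e-12)


class TestPairEnrichment:
    def make_pairs(self, keys):
        pl = GenePairList("p", 7227, 7227, Provenance("s", TODAY, "query"))
        for a, b in keys:
            pl.add_entry(
                GenePairEntry(
                    Gene(a, 7227),
                    Gene(b, 7227),
                    [EvidenceItem("s", 1, "article_count", TODAY)],
                )
            )
        return pl

    def test_pair_reported_only_when_both_members_enriched(self):
        tg = build_graph(
            [("t", "root")], [(g, "t", "EXP") for g in (1, 2, 3)]
        )
        pairs = self.make_pairs([(1, 2), (1, 9), (2, 3)])
        pop = set(range(1, 11))
        res = pair_enrichment(
            pairs, term_for_term, pop, tg
        )
        by_term = {r.term: r for r in res}
        assert by_term["t"].member_genes == {(1, 2), (2, 3)}

    def test_colocalisation_matches_set_intersection_oracle(self, term_graph, manifest):
        study = manifest["study_genes"]
        pairs = self.make_pairs(list(zip(study, study[1:])))
        pop = set(manifest["population"])
        res = pair_enrichment(pairs, term_for_term, pop, term_graph)
        for r in res:
            ann = term_graph.ann(r.term)
            expected = {
                k for k in pairs.entries if k[0] in ann and k[1] in ann
            }
            assert r.member_genes == expected
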