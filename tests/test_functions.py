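"""Tests for term filtering, enrichment, term reachability and clustering."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from sigreach.functions import (
    AnnotationMap,
    OntologyError,
    TermNotApplicable,
    cluster_matrix,
    enrich_all,
    filter_generic_terms,
    hypergeometric_tail,
    protein_protein_matrix,
    protein_term_matrix,
    read_annotations,
    target_reachability_ranking,
    term_depths,
    term_enrichment,
    term_reachability,
)
from sigreach.network_model import ValidationError
from sigreach.preach_core import reachability_bruteforce

from conftest import make_net


class TestTermDepths:
    def test_depths_follow_shortest_parent_chains(self, mini_obo):
        depths = term_depths(mini_obo)
        assert depths["X:0000001"] == 0
        assert depths["X:0000002"] == 1
        assert depths["X:0000003"] == 2  # via part_of
        assert depths["X:0000004"] == 3
        assert depths["X:0000005"] == 2  # diamond: shortest of paths 2 and 4

    def test_cycle_raises(self, tmp_path):
        path = tmp_path / "cyclic.obo"
        path.write_text(
            "format-version: 1.2\nontology: bad\n\n"
            "[Term]\nid: A:1\nname: a\nis_a: A:2\n\n"
            "[Term]\nid: A:2\nname: b\nis_a: A:1\n"
        )
        with pytest.raises(OntologyError, match="cycle"):
            term_depths(path)

    def test_undefined_parent_raises(self, tmp_path):
        path = tmp_path / "dangling.obo"
        path.write_text(
            "format-version: 1.2\nontology: bad\n\n"
            "[Term]\nid: A:1\nname: a\nis_a: A:9\n"
        )
        with pytest.raises(OntologyError, match="undefined parent"):
            term_depths(path)


class TestFilterGenericTerms:
    def test_depth_boundary_at_the_top_five_levels(self):
        ann = AnnotationMap({"g": {"t4", "t5"}})
        out = filter_generic_terms(ann, {"t4": 4, "t5": 5})
        assert out.gene_terms["g"] == {"t5"}

    def test_gene_with_only_shallow_terms_keeps_an_empty_set(self):
        ann = AnnotationMap({"g": {"t0"}})
        out = filter_generic_terms(ann, {"t0": 0})
        assert out.gene_terms["g"] == set()

    def test_terms_without_depth_are_kept_with_warning(self, caplog):
        ann = AnnotationMap({"g": {"mystery"}})
        with caplog.at_level("WARNING"):
            out = filter_generic_terms(ann, {})
        assert out.gene_terms["g"] == {"mystery"}
        assert "no depth information" in caplog.text


class TestAnnotationsIO:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("# comment\ng1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        ann = read_annotations(path)
        assert ann.gene_terms == {"g1": {"GO:1", "GO:2"}, "g2": {"GO:1"}}
        assert ann.genes_with("GO:1") == {"g1", "g2"}
        assert ann.terms() == {"GO:1", "GO:2"}


class TestTargetRanking:
    def test_unreachable_target_ranks_last_with_zero(self):
        net = make_net(
            [("s", "a"), ("a", "t1")], [0.5, 0.5], {"s"}, {"t1", "t2"}, extra={"t2"}
        )
        ranking = target_reachability_ranking(net)
        assert ranking == [("t1", pytest.approx(0.25)), ("t2", 0.0)]

    def test_redundant_paths_outrank_a_single_path(self):
        net = make_net(
            [("s", "v"), ("v", "t"), ("s", "w"), ("w", "t"), ("s", "x"), ("x", "u")],
            [0.5] * 6,
            {"s"},
            {"t", "u"},
        )
        ranking = target_reachability_ranking(net)
        assert [t for t, _ in ranking] == ["t", "u"]
        assert ranking[0][1] == pytest.approx(0.4375, abs=1e-12)
        assert ranking[1][1] == pytest.approx(0.25, abs=1e-12)

    def test_ties_break_by_identifier(self):
        net = make_net(
            [("s", "t2"), ("s", "t1")], [0.5, 0.5], {"s"}, {"t1", "t2"}
        )
        assert [t for t, _ in target_reachability_ranking(net)] == ["t1", "t2"]


def enumerate_tail(population, successes, draws, observed):
    """Exhaustive oracle: fraction of d-subsets with >= observed marked."""
    marked = set(range(successes))
    hits = sum(
        1
        for sub in itertools.combinations(range(population), draws)
        if len(marked.intersection(sub)) >= observed
    )
    return hits / comb(population, draws)


class TestHypergeometricTail:
    def test_worked_example_top3_of_10(self):
        # 3 annotated targets occupying ranks 1-3: C(3,3)C(7,0)/C(10,3) = 1/120
        assert hypergeometric_tail(10, 3, 3, 3) == pytest.approx(1 / 120, abs=1e-15)

    def test_zero_observed_is_certain(self):
        assert hypergeometric_tail(10, 3, 5, 0) == 1.0

    @pytest.mark.parametrize("population", [5, 8])
    def test_matches_enumeration_and_scipy(self, population):
        for successes in range(population + 1):
            for draws in range(1, population + 1):
                for observed in range(min(successes, draws) + 2):
                    tail = hypergeometric_tail(population, successes, draws, observed)
                    assert tail == pytest.approx(
                        enumerate_tail(population, successes, draws, observed),
                        abs=1e-12,
                    )
                    assert tail == pytest.approx(
                        float(hypergeom.sf(observed - 1, population, successes, draws)),
                        abs=1e-9,
                    )


class TestTermEnrichment:
    def ranking10(self):
        return [(f"t{i:02d}", 1.0 - i / 10) for i in range(10)]

    def test_top_ranks_annotated_gives_the_worked_minimum(self):
        ann = AnnotationMap({f"t{i:02d}": {"A"} for i in range(3)})
        rec = term_enrichment("A", self.ranking10(), ann)
        assert rec.best_d == 3 and rec.n_at_best_d == 3 and rec.n_annotated == 3
        assert rec.enrichment == pytest.approx(1 / 120, abs=1e-15)
        assert rec.highly_enriched

    def test_saturated_term_is_uninformative(self):
        ann = AnnotationMap({t: {"A"} for t, _ in self.ranking10()})
        rec = term_enrichment("A", self.ranking10(), ann)
        assert rec.enrichment == 1.0
        assert not rec.highly_enriched

    def test_minimum_over_d_never_exceeds_any_fixed_d(self):
        ann = AnnotationMap({t: {"A"} for t in ["t01", "t04", "t07"]})
        rec = term_enrichment("A", self.ranking10(), ann)
        order = [t for t, _ in self.ranking10()]
        for d in range(1, 11):
            n = sum(1 for t in order[:d] if t in {"t01", "t04", "t07"})
            assert rec.enrichment <= hypergeometric_tail(10, 3, d, n) + 1e-15

    def test_term_without_ranked_targets_rejected(self):
        with pytest.raises(ValidationError):
            term_enrichment("A", self.ranking10(), AnnotationMap({"other": {"A"}}))


class TestTermReachability:
    def test_single_annotated_edge(self):
        net = make_net([("s", "t")], [0.7], {"s"}, {"t"})
        ann = AnnotationMap({"s": {"A"}, "t": {"A"}})
        assert term_reachability(net, ann, "A") == pytest.approx(0.7, abs=1e-12)

    def test_unreachable_annotated_target_scores_zero_not_na(self):
        net = make_net([("s", "x")], [0.9], {"s"}, {"t"}, extra={"t"})
        ann = AnnotationMap({"s": {"A"}, "t": {"A"}})
        assert term_reachability(net, ann, "A") == 0.0

    def test_two_independent_sources(self):
        net = make_net(
            [("s1", "t1"), ("s2", "t1")], [0.5, 0.5], {"s1", "s2"}, {"t1"}
        )
        ann = AnnotationMap({"s1": {"A"}, "s2": {"A"}, "t1": {"A"}})
        assert term_reachability(net, ann, "A") == pytest.approx(0.75, abs=1e-12)
        assert reachability_bruteforce(net) == pytest.approx(0.75)

    def test_source_only_term_is_not_applicable(self):
        net = make_net([("s", "t")], [0.7], {"s"}, {"t"})
        ann = AnnotationMap({"s": {"A"}})
        with pytest.raises(TermNotApplicable):
            term_reachability(net, ann, "A")

    def test_unknown_annotated_genes_ignored_with_warning(self, caplog):
        net = make_net([("s", "t")], [0.7], {"s"}, {"t"})
        ann = AnnotationMap({"s": {"A"}, "t": {"A"}, "ghost": {"A"}})
        with caplog.at_level("WARNING"):
            assert term_reachability(net, ann, "A") == pytest.approx(0.7)
        assert "ghost" in caplog.text


@pytest.fixture
def five_node_net():
    return make_net(
        [("s", "a"), ("a", "t"), ("s", "b"), ("b", "t"), ("a", "b")],
        [0.6, 0.5, 0.4, 0.7, 0.3],
        {"s"},
        {"t"},
    )


class TestMatrices:
    def test_protein_protein_diagonal_and_direction(self):
        net = make_net([("s", "a"), ("a", "t")], [0.5, 0.5], {"s"}, {"t"})
        mat = protein_protein_matrix(net)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert mat.loc["s", "t"] == pytest.approx(0.25, abs=1e-12)
        assert mat.loc["t", "s"] == 0.0

    def test_protein_protein_matches_bruteforce_cellwise(self, five_node_net):
        mat = protein_protein_matrix(five_node_net)
        for i in mat.index:
            for j in mat.columns:
                if i == j:
                    continue
                want = reachability_bruteforce(five_node_net, {i}, {j})
                assert mat.loc[i, j] == pytest.approx(want, abs=1e-10)

    def test_protein_term_annotated_target_row_is_one(self, five_node_net):
        ann = AnnotationMap({"t": {"A"}, "b": {"B"}})
        mat = protein_term_matrix(five_node_net, ann)
        assert list(mat.columns) == ["A"]  # B annotates no target
        assert mat.loc["t", "A"] == 1.0

    def test_protein_term_cells_match_bruteforce(self, five_node_net):
        ann = AnnotationMap({"t": {"A"}})
        mat = protein_term_matrix(five_node_net, ann)
        for i in mat.index:
            want = (
                1.0 if i == "t" else reachability_bruteforce(five_node_net, {i}, {"t"})
            )
            assert mat.loc[i, "A"] == pytest.approx(want, abs=1e-10)

    def test_no_path_row_is_zero(self, five_node_net):
        mat = protein_protein_matrix(five_node_net)
        assert mat.loc["t", ["a", "b", "s"]].tolist() == [0.0, 0.0, 0.0]


class TestClustering:
    def test_identical_rows_merge_first_at_distance_zero(self):
        m = np.array([[1.0, 0.0], [0.3, 0.9], [1.0, 0.0]])
        res = cluster_matrix(m)
        assert res.linkage[0][0] == 0 and res.linkage[0][1] == 2
        assert res.linkage[0][2] == 0.0

    def test_block_matrix_keeps_groups_contiguous(self):
        rng = np.random.default_rng(0)
        block_a = 0.9 + 0.01 * rng.random((3, 4))
        block_b = 0.1 + 0.01 * rng.random((3, 4))
        m = np.vstack([block_a, block_b])
        order = cluster_matrix(m).leaf_order
        groups = [0 if i < 3 else 1 for i in order]
        assert groups in ([0, 0, 0, 1, 1, 1], [1, 1, 1, 0, 0, 0])

    def test_partition_is_permutation_equivariant(self):
        from scipy.cluster.hierarchy import fcluster

        rng = np.random.default_rng(1)
        m = rng.random((6, 3))
        perm = [3, 0, 5, 1, 4, 2]
        res1 = cluster_matrix(m)
        res2 = cluster_matrix(m[perm])
        f1 = fcluster(res1.linkage, t=2, criterion="maxclust")
        f2 = fcluster(res2.linkage, t=2, criterion="maxclust")
        part1 = {frozenset(np.where(f1 == k)[0]) for k in set(f1)}
        part2 = {
            frozenset(perm[i] for i in np.where(f2 == k)[0]) for k in set(f2)
        }
        assert part1 == part2

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError):
            cluster_matrix(np.ones((1, 3)))


class TestEnrichAll:
    def test_planted_block_recovered_on_a_constructed_network(self):
        edges, probs = [], []
        for i in range(5):
            # t0..t2 get strong paths, t3..t4 weak ones
            p = 0.95 if i < 3 else 0.2
            edges += [("s", f"m{i}"), (f"m{i}", f"t{i}")]
            probs += [p, p]
        net = make_net(edges, probs, {"s"}, {f"t{i}" for i in range(5)})
        ann = AnnotationMap(
            {"t0": {"hot"}, "t1": {"hot"}, "t2": {"hot"}, "t3": {"cold"}, "t4": {"cold"}}
        )
        table = enrich_all(net, ann)
        best = table.iloc[0]
        assert best["term"] == "hot"
        assert best["enrichment"] == pytest.approx(1 / 10, abs=1e-12)  # C(3,3)/C(5,3)
        assert bool(best["highly_enriched"])
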