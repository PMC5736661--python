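"""Network construction, geodesic enumeration and scoring against oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import degnet as d
from degnet.errors import NetworkError, PathCapExceeded, SchemaError
from conftest import annotation, brute_force_scores, random_annotation


class TestBuildNetwork:
    def test_single_pathway_triangle(self):
        net = d.build_network(annotation(P1="ABC"))
        assert net.n_nodes == 3
        assert net.n_pair_edges == 3
        assert net.n_incidences == 3

    def test_intersection_rule(self):
        net = d.build_network(annotation(P1="AB", P2="BC"))
        assert set(map(tuple, map(sorted, net.graph.edges))) == {("A", "B"), ("B", "C")}

    def test_hand_enumerated_two_pathway_overlap(self):
        net = d.build_network(annotation(P1="ABC", P2="BCD"))
        assert net.n_pair_edges == 5
        assert net.n_incidences == 6
        assert net.graph.edges["B", "C"]["pathways"] == {"P1", "P2"}
        assert not net.graph.has_edge("A", "D")

    def test_singleton_pathway_gene_excluded_but_pathway_kept(self):
        net = d.build_network(annotation(P1="AB", P2="Z"))
        assert "Z" not in net.graph
        assert net.n_pathways == 2

    def test_empty_annotation_rejected(self):
        with pytest.raises(NetworkError):
            d.build_network(d.PathwayAnnotation(pathways={}))


class TestAllShortestPaths:
    def test_adjacent_pair_single_edge(self):
        net = d.build_network(annotation(P1="AB"))
        assert list(d.all_shortest_paths(net, ("A", "B"))) == [("A", "B")]

    def test_four_cycle_two_geodesics(self):
        ann = annotation(P="AB", Q="BC", R="CD", S="DA")
        net = d.build_network(ann)
        paths = sorted(d.all_shortest_paths(net, ("A", "C")))
        assert paths == [("A", "B", "C"), ("A", "D", "C")]

    def test_disconnected_pair_empty(self):
        net = d.build_network(annotation(P1="AB", P2="CD"))
        assert len(d.all_shortest_paths(net, ("A", "C"))) == 0

    def test_same_node_rejected(self):
        net = d.build_network(annotation(P1="AB"))
        with pytest.raises(NetworkError):
            d.all_shortest_paths(net, ("A", "A"))

    def test_cap_flags_non_exhaustive(self):
        ann = annotation(P="AB", Q="BC", R="CD", S="DA")
        net = d.build_network(ann)
        g = d.all_shortest_paths(net, ("A", "C"), path_cap=1)
        assert not g.exhaustive
        assert len(g) == 1

    def test_matches_brute_force_on_random_graphs(self):
        """Geodesic sets equal exhaustive depth-limited simple-path enumeration."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            ann = random_annotation(rng, n_genes=6, n_pathways=4, size_range=(2, 4))
            try:
                net = d.build_network(ann)
            except NetworkError:
                continue
            nodes = net.nodes()
            for u, v in itertools.combinations(nodes, 2):
                got = sorted(d.all_shortest_paths(net, (u, v)))
                if nx.has_path(net.graph, u, v):
                    L = nx.shortest_path_length(net.graph, u, v)
                    want = sorted(
                        tuple(p)
                        for p in nx.all_simple_paths(net.graph, u, v, cutoff=L)
                        if len(p) - 1 == L
                    )
                else:
                    want = []
                assert got == want


class TestScoreNetwork:
    def test_empty_and_singleton_deg_sets(self, path_graph_net):
        for deg_set in (set(), {"A"}):
            st = d.score_network(path_graph_net, deg_set)
            assert set(st.gene_score.values()) == {0}
            assert set(st.edge_score.values()) == {0}
            assert set(st.pathway_score.values()) == {0}

    def test_path_graph_manual_census(self, path_graph_net):
        st = d.score_network(path_graph_net, {"A", "B", "C"})
        assert st.gene_score == {"A": 2, "B": 3, "C": 2}
        assert st.edge_score == {("A", "B"): 2, ("B", "C"): 2}
        assert st.pathway_score == {"Pa": 2, "Pb": 2}
        assert st.n_paths == 3

    def test_shared_label_path_graph_pathway_score(self):
        """Both links labeled with one pathway: the A-B-C census gives it 4."""
        ann = d.PathwayAnnotation(
            pathways={"P1": ("", frozenset("ABC")), "P2": ("", frozenset("CD"))}
        )
        # P1 makes a triangle; instead build the path graph explicitly
        net = d.build_network(annotation(P1="AB"))
        net.graph.add_edge("B", "C", pathways=frozenset({"P1"}))
        net.graph.edges["A", "B"]["pathways"] = frozenset({"P1"})
        net2 = d.GenePathwayNetwork(graph=net.graph, pathway_ids=["P1"])
        st = d.score_network(net2, {"A", "B", "C"})
        assert st.pathway_score == {"P1": 4}
        st_pp = d.score_network(net2, {"A", "B", "C"}, pathway_increment="per_path")
        # per-path rule: each of the 3 geodesics contributes at most 1 to P1
        assert st_pp.pathway_score == {"P1": 3}

    def test_non_deg_interior_node_blocks_all_paths(self, path_graph_net):
        st = d.score_network(path_graph_net, {"A", "C"})
        assert sum(st.gene_score.values()) == 0
        assert st.n_paths == 0

    def test_unmapped_degs_dropped(self, path_graph_net):
        st = d.score_network(path_graph_net, {"A", "B", "nope"})
        assert st.n_deg_mapped == 2

    def test_path_cap_aborts(self, path_graph_net):
        with pytest.raises(PathCapExceeded):
            d.score_network(path_graph_net, {"A", "B", "C"}, path_cap=2)

    def test_score_conservation(self):
        """Sum of gene scores = total path nodes; edge scores = path edges."""
        rng = np.random.default_rng(3)
        ann = random_annotation(rng, n_genes=8, n_pathways=4, size_range=(2, 5))
        net = d.build_network(ann)
        deg_set = set(net.nodes()[:5])
        st = d.score_network(net, deg_set)
        _g, _e, _p, n_paths = brute_force_scores(net, deg_set)
        lengths = []
        for u, v in itertools.combinations(sorted(deg_set), 2):
            for path in d.all_shortest_paths(net, (u, v)):
                if all(x in deg_set for x in path):
                    lengths.append(len(path))
        assert st.n_paths == n_paths == len(lengths)
        assert sum(st.gene_score.values()) == sum(lengths)
        assert sum(st.edge_score.values()) == sum(L - 1 for L in lengths)

    @pytest.mark.parametrize("increment", ["per_edge", "per_path"])
    def test_brute_force_agreement_random_graphs(self, increment):
        rng = np.random.default_rng(11)
        for _ in range(4):
            ann = random_annotation(rng, n_genes=7, n_pathways=4, size_range=(2, 5))
            net = d.build_network(ann)
            nodes = net.nodes()
            for _ in range(10):
                k = int(rng.integers(2, len(nodes) + 1))
                deg_set = set(rng.choice(nodes, size=k, replace=False).tolist())
                st = d.score_network(net, deg_set, pathway_increment=increment)
                g, e, p, n = brute_force_scores(net, deg_set, pathway_increment=increment)
                assert st.gene_score == g
                assert st.edge_score == e
                assert st.pathway_score == p
                assert st.n_paths == n

    def test_monotonicity_adding_a_deg_never_decreases_scores(self):
        rng = np.random.default_rng(5)
        ann = random_annotation(rng, n_genes=8, n_pathways=4, size_range=(3, 6))
        net = d.build_network(ann)
        nodes = net.nodes()
        deg_set = set(nodes[:4])
        base = d.score_network(net, deg_set)
        for extra in nodes[4:]:
            bigger = d.score_network(net, deg_set | {extra})
            assert all(
                bigger.gene_score[k] >= v for k, v in base.gene_score.items()
            )
            assert all(
                bigger.pathway_score[k] >= v for k, v in base.pathway_score.items()
            )


class TestPermutationNull:
    def test_full_node_set_gives_zero_variance_null(self):
        net = d.build_network(annotation(P1="ABC", P2="BCD"))
        null = d.permutation_null(net, net.n_nodes, n_perm=10, seed=0)
        assert (null.scores.nunique() == 1).all()
        full = d.score_network(net, set(net.nodes()))
        for pid in net.pathway_ids:
            assert (null.scores[pid] == full.pathway_score[pid]).all()

    def test_single_deg_null_all_zero(self):
        net = d.build_network(annotation(P1="ABC"))
        null = d.permutation_null(net, 1, n_perm=5, seed=0)
        assert (null.scores.to_numpy() == 0).all()

    def test_oversized_deg_count_rejected(self):
        net = d.build_network(annotation(P1="AB"))
        with pytest.raises(NetworkError):
            d.permutation_null(net, 3, n_perm=2, seed=0)

    def test_seeded_reproducibility(self):
        net = d.build_network(annotation(P1="ABCDE", P2="DEFG"))
        n1 = d.permutation_null(net, 3, n_perm=20, seed=9)
        n2 = d.permutation_null(net, 3, n_perm=20, seed=9)
        pd.testing.assert_frame_equal(n1.scores, n2.scores)

    def test_null_mean_matches_exhaustive_subset_average(self):
        """Monte-Carlo null mean agrees with the average over all C(10,4) subsets."""
        rng = np.random.default_rng(17)
        ann = random_annotation(rng, n_genes=10, n_pathways=5, size_range=(3, 6))
        net = d.build_network(ann)
        nodes = net.nodes()
        exact = {pid: 0.0 for pid in net.pathway_ids}
        subsets = list(itertools.combinations(nodes, 4))
        for sub in subsets:
            st = d.score_network(net, set(sub))
            for pid, v in st.pathway_score.items():
                exact[pid] += v
        exact = {pid: v / len(subsets) for pid, v in exact.items()}
        null = d.permutation_null(net, 4, n_perm=2000, seed=1)
        for pid in net.pathway_ids:
            mc = null.scores[pid].mean()
            se = null.scores[pid].std(ddof=1) / np.sqrt(2000)
            assert abs(mc - exact[pid]) < max(4 * se, 0.05)


class TestPathwayPvalues:
    def _table(self, scores):
        return d.ScoreTable(
            gene_score={}, edge_score={}, pathway_score=scores, n_deg_mapped=0
        )

    def _null(self, **columns):
        return d.NullDistribution(
            scores=pd.DataFrame(columns), seed=0, n_deg_mapped=0
        )

    def test_counting_example(self):
        null = self._null(P=[0, 0, 1, 2, 5])
        out = d.pathway_pvalues(self._table({"P": 2}), null)
        assert out.loc[0, "empirical_p"] == pytest.approx((1 + 2) / 6)

    def test_observed_zero_gives_p_one(self):
        null = self._null(P=[0, 1, 2])
        out = d.pathway_pvalues(self._table({"P": 0}), null)
        assert out.loc[0, "empirical_p"] == 1.0
        assert not out.loc[0, "significant"]

    def test_pseudocount_floor(self):
        null = self._null(P=[0] * 1000)
        out = d.pathway_pvalues(self._table({"P": 5}), null)
        assert out.loc[0, "empirical_p"] == pytest.approx(1 / 1001)

    def test_mismatched_universe_rejected(self):
        null = self._null(P=[0])
        with pytest.raises(SchemaError):
            d.pathway_pvalues(self._table({"Q": 1}), null)

    def test_sorted_with_id_tiebreak(self):
        null = self._null(B=[0, 0], A=[0, 0], C=[5, 5])
        out = d.pathway_pvalues(self._table({"A": 1, "B": 1, "C": 0}), null)
        assert list(out["pathway_id"]) == ["A", "B", "C"]

    def test_gaussian_tail_resolves_below_empirical_floor(self):
        rng = np.random.default_rng(2)
        null = self._null(P=rng.normal(10, 2, 100).round())
        out = d.pathway_pvalues(self._table({"P": 30}), null, null_model="gaussian")
        assert 0 < out.loc[0, "empirical_p"] < 1 / 101
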