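"""PCIT inference, network reduction, topology/centrality, regulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from awmnet.awm import Awm
from awmnet.datatypes import GeneAnnotation, ValidationError
from awmnet.network import (
    CoassocNetwork,
    centrality,
    correlation_matrix,
    pcit,
    rank_regulators,
    reduce_network,
    topology_stats,
)
from conftest import betweenness_oracle, pcit_oracle


def toy_awm(values, gene_ids=None, key="t0"):
    values = np.asarray(values, float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    traits = [f"t{j}" for j in range(values.shape[1])]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=traits)
    rows = pd.DataFrame(
        {"snp": [f"s{i}" for i in range(len(genes))], "reason": "key_trait",
         "distance": 0, "key_p": 0.001},
        index=vals.index,
    )
    return Awm(values=vals, rows=rows, key_trait=key, ap=2)


def random_corr(n, rng):
    """Wishart-sampled correlation matrix."""
    a = rng.standard_normal((n, max(n + 5, int(1.5 * n))))
    c = np.corrcoef(a)
    np.fill_diagonal(c, 1.0)
    return c


def net_from_edges(edges, classes=None):
    """CoassocNetwork literal with all edges kept."""
    nodes = sorted({v for e in edges for v in e[:2]})
    df = pd.DataFrame(
        [(a, b, w, True, True) for a, b, w in edges],
        columns=["gene1", "gene2", "r", "pcit_kept", "reduced_kept"],
    )
    node_df = pd.DataFrame(
        {"gene_class": [(classes or {}).get(v, "protein_coding") for v in nodes],
         "awm_row": -1},
        index=pd.Index(nodes, name="gene"),
    )
    return CoassocNetwork(nodes=node_df, edges=df, threshold=0.0, k=2.0)


class TestCorrelationMatrix:
    def test_identical_and_opposite_rows(self):
        base = np.array([1.0, -0.5, 2.0, 0.3])
        awm = toy_awm(np.vstack([base, base, -base]))
        c = correlation_matrix(awm)
        np.testing.assert_allclose(c.iloc[0, 1], 1.0)
        np.testing.assert_allclose(c.iloc[0, 2], -1.0)

    def test_null_mean_abs_correlation(self):
        # independent normal rows over k columns: |r| has the null
        # correlation distribution, E|r| = E[sqrt(B)], B ~ Beta(1/2, (k-2)/2)
        rng = np.random.default_rng(42)
        k = 17
        awm = toy_awm(rng.standard_normal((300, k)))
        c = correlation_matrix(awm).to_numpy()
        iu = np.triu_indices(300, 1)
        observed = np.abs(c[iu]).mean()
        expected = float(np.sqrt(stats.beta(0.5, (k - 2) / 2).rvs(
            200_000, random_state=7)).mean())
        assert abs(observed - expected) < 0.02

    def test_constant_row_names_gene(self):
        m = np.vstack([np.ones(5), np.random.default_rng(0).standard_normal(5)])
        awm = toy_awm(m, gene_ids=["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            correlation_matrix(awm)


class TestPcit:
    def test_two_nodes_trivially_kept(self):
        res = pcit(np.array([[1.0, 0.7], [0.7, 1.0]]))
        assert res.kept[0, 1] and res.kept[1, 0]

    def test_shared_factor_edge_survives_indirect_removed(self):
        rng = np.random.default_rng(5)
        n_cols = 1000
        f = rng.standard_normal(n_cols)
        x = f + 0.5 * rng.standard_normal(n_cols)
        y = f + 0.5 * rng.standard_normal(n_cols)
        z = 0.3 * x + 0.3 * y + rng.standard_normal(n_cols)
        c = np.corrcoef(np.vstack([x, y, z]))
        res = pcit(c)
        oracle = pcit_oracle(c)
        np.testing.assert_array_equal(res.kept, oracle)
        assert res.kept[0, 1]  # direct x-y co-association survives

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_matrices(self, seed):
        rng = np.random.default_rng(900 + seed)
        c = random_corr(15, rng)
        res = pcit(c)
        np.testing.assert_array_equal(res.kept, pcit_oracle(c))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(77)
        c = random_corr(12, rng)
        perm = rng.permutation(12)
        res = pcit(c)
        res_p = pcit(c[np.ix_(perm, perm)])
        np.testing.assert_array_equal(res_p.kept, res.kept[np.ix_(perm, perm)])

    def test_out_of_range_correlation_rejected(self):
        c = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValidationError):
            pcit(c)

    def test_collinear_trios_counted_not_fatal(self):
        base = np.array([1.0, -1.0, 0.5, 0.2])
        m = np.vstack([base, base, np.random.default_rng(3).standard_normal(4)])
        c = np.corrcoef(m)
        res = pcit(c)
        assert res.n_skipped_trios > 0


class TestReduction:
    def test_hand_arithmetic_threshold(self):
        # |r| = {0.2 x5, 0.95}: mean 0.325, sample sd 0.30619, t = 0.93738
        rs = [0.2, 0.2, 0.2, 0.2, 0.2, 0.95]
        c = np.eye(4)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), r in zip(pairs, rs):
            c[i, j] = c[j, i] = r
        res = pcit(c)
        res.kept[:] = True  # isolate the reduction rule
        np.fill_diagonal(res.kept, False)
        net = reduce_network(res, k=2.0)
        np.testing.assert_allclose(net.threshold, 0.9373747, atol=1e-4)
        kept = net.reduced_edges()
        assert len(kept) == 1 and abs(kept["r"].iloc[0]) == 0.95

    def test_k_zero_keeps_above_mean(self):
        rs = [0.2, 0.4, 0.9]
        c = np.eye(3)
        for (i, j), r in zip([(0, 1), (0, 2), (1, 2)], rs):
            c[i, j] = c[j, i] = r
        res = pcit(c)
        res.kept[:] = True
        np.fill_diagonal(res.kept, False)
        net = reduce_network(res, k=0.0)
        assert set(np.round(net.reduced_edges()["r"], 6)) == {0.9}

    def test_equal_weights_all_retained(self):
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        res = pcit(c)
        res.kept[:] = True
        np.fill_diagonal(res.kept, False)
        net = reduce_network(res, k=2.0)
        assert net.reduced_edges().shape[0] == 6  # sd 0: threshold = mean

    def test_k_monotonicity(self):
        rng = np.random.default_rng(10)
        c = random_corr(12, rng)
        res = pcit(c)
        last = None
        for k in (0.0, 1.0, 2.0, 3.0):
            n = reduce_network(res, k=k).reduced_edges().shape[0]
            if last is not None:
                assert n <= last
            last = n

    def test_replay_threshold_invariant(self):
        rng = np.random.default_rng(11)
        c = random_corr(20, rng)
        net = reduce_network(pcit(c), k=2.0)
        kept = net.reduced_edges()
        assert (np.abs(kept["r"]) >= net.threshold - 1e-12).all()
        assert kept["pcit_kept"].all()


class TestTopology:
    def test_triangle(self):
        net = net_from_edges([("a", "b", 0.9), ("b", "c", 0.9), ("a", "c", 0.9)])
        topo = topology_stats(net)
        assert topo["n_nodes"] == 3 and topo["n_edges"] == 3
        assert topo["mean_degree"] == 2.0 and topo["n_components"] == 1

    def test_empty(self):
        net = net_from_edges([("a", "b", 0.9)])
        net.edges["reduced_kept"] = False
        topo = topology_stats(net)
        assert topo["n_nodes"] == 0 and topo["n_edges"] == 0

    def test_star_degrees(self):
        net = net_from_edges([("hub", f"x{i}", 0.9) for i in range(4)])
        topo = topology_stats(net)
        degs = sorted(topo["degree_distribution"].values())
        assert degs == [1, 1, 1, 1, 4]


class TestCentrality:
    def test_path_graph_closed_form(self):
        net = net_from_edges([("a", "b", 0.9), ("b", "c", 0.9)])
        cent = centrality(net)
        assert cent.loc["b", "betweenness"] == 1.0
        assert cent.loc["a", "betweenness"] == 0.0

    def test_star_center_maximal(self):
        net = net_from_edges([("hub", f"x{i}", 0.9) for i in range(5)])
        cent = centrality(net)
        assert cent["degree"].idxmax() == "hub"
        assert cent["betweenness"].idxmax() == "hub"

    def test_matches_bruteforce_on_random_graph(self):
        rng = np.random.default_rng(123)
        nodes = [f"n{i}" for i in range(30)]
        edges = []
        for i in range(30):
            for j in range(i + 1, 30):
                if rng.random() < 0.12:
                    edges.append((nodes[i], nodes[j], 0.9))
        net = net_from_edges(edges)
        cent = centrality(net)
        oracle = betweenness_oracle([(a, b) for a, b, _ in edges],
                                    set(cent.index))
        for node in cent.index:
            np.testing.assert_allclose(
                cent.loc[node, "betweenness"], oracle[node], atol=1e-9
            )


def make_ann_classes(classes: dict) -> GeneAnnotation:
    rows = [
        dict(gene=g, chrom="1", start=1000 * (i + 1), end=1000 * (i + 1) + 500,
             strand="+", gene_class=c)
        for i, (g, c) in enumerate(classes.items())
    ]
    return GeneAnnotation(pd.DataFrame(rows).set_index("gene"))


class TestRegulators:
    def test_single_tf_covers_neighbors(self):
        edges = [("tf1", f"g{i}", 0.9) for i in range(5)]
        edges += [(f"g{i}", f"g{i + 5}", 0.9) for i in range(5)]
        classes = {"tf1": "TF", **{f"g{i}": "protein_coding" for i in range(10)}}
        net = net_from_edges(edges, classes)
        awm = toy_awm(np.random.default_rng(0).standard_normal((11, 4)),
                      gene_ids=list(classes))
        tab = rank_regulators(net, make_ann_classes(classes), awm)
        assert tab.index[0] == "tf1"
        assert tab.loc["tf1", "selected"] and tab.loc["tf1", "coverage_gain"] == 5

    def test_identical_neighbor_sets_tie_lexicographic(self):
        edges = [("tfA", "g1", 0.9), ("tfA", "g2", 0.9),
                 ("tfB", "g1", 0.9), ("tfB", "g2", 0.9)]
        classes = {"tfA": "TF", "tfB": "TF", "g1": "protein_coding",
                   "g2": "protein_coding"}
        net = net_from_edges(edges, classes)
        awm = toy_awm(np.random.default_rng(1).standard_normal((4, 4)),
                      gene_ids=list(classes))
        tab = rank_regulators(net, make_ann_classes(classes), awm)
        # identical coverage: only the lexicographically first is selected
        assert tab.loc["tfA", "selected"]
        assert not tab.loc["tfB", "selected"]

    def test_no_regulators_warns(self):
        edges = [("g1", "g2", 0.9)]
        classes = {"g1": "protein_coding", "g2": "protein_coding"}
        net = net_from_edges(edges, classes)
        awm = toy_awm(np.random.default_rng(2).standard_normal((2, 4)),
                      gene_ids=list(classes))
        with pytest.warns(UserWarning, match="no regulator"):
            tab = rank_regulators(net, make_ann_classes(classes), awm)
        assert tab.empty

    def test_master_regulator_recovered(self):
        # hub regulator with the largest true connectivity ranks first
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            edges = [("hub", f"g{i}", 0.9) for i in range(8)]
            edges += [("tf2", f"g{i}", 0.9) for i in rng.choice(8, 3, replace=False)]
            for _ in range(5):
                i, j = rng.choice(8, 2, replace=False)
                edges.append((f"g{i}", f"g{j}", 0.9))
            classes = {"hub": "TF", "tf2": "TF",
                       **{f"g{i}": "protein_coding" for i in range(8)}}
            net = net_from_edges(list(dict.fromkeys(edges)), classes)
            awm = toy_awm(rng.standard_normal((10, 4)), gene_ids=list(classes))
            tab = rank_regulators(net, make_ann_classes(classes), awm)
            wins += tab.index[0] == "hub"
        assert wins >= 18
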