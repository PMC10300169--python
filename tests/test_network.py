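import numpy as np
import pandas as pd
import pytest

from lipidnet.network import (
    LipidNetwork,
    partial_correlation,
    pc_skeleton,
    robust_edges,
    split_half_network,
    walktrap_clusters,
)


def gaussian_chain(n=5000, seed=2):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 0.8 * x + rng.normal(size=n)
    z = 0.8 * y + rng.normal(size=n)
    return pd.DataFrame({"X": x, "Y": y, "Z": z})


def random_dag_data(n_nodes=10, n=5000, edge_prob=0.2, seed=4):
    """Linear Gaussian SEM over a random upper-triangular DAG; returns the
    data and the true skeleton adjacency."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                W[i, j] = rng.choice([-1, 1]) * rng.uniform(0.5, 1.0)
    X = np.zeros((n, n_nodes))
    for j in range(n_nodes):
        X[:, j] = X @ W[:, j] + rng.normal(size=n)
    skel = (W != 0) | (W != 0).T
    return pd.DataFrame(X, columns=[f"v{j}" for j in range(n_nodes)]), skel


class TestPCSkeleton:
    def test_chain_removes_only_the_shielded_edge(self):
        sk = pc_skeleton(gaussian_chain(), alpha=0.05, max_order=3)
        assert sk.edges == {frozenset({"X", "Y"}), frozenset({"Y", "Z"})}
        assert tuple(sk.sepsets[(0, 2)]) == (1,)  # X _|_ Z | {Y}

    def test_independent_features_give_empty_graph(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        sk = pc_skeleton(df, alpha=0.05, max_order=2)
        assert sk.edges == set()

    def test_random_dag_structural_hamming_distance(self):
        df, true_skel = random_dag_data()
        sk = pc_skeleton(df, alpha=0.05, max_order=3)
        diff = sk.adjacency != true_skel
        shd = int(np.triu(diff, 1).sum())
        assert shd <= 2

    def test_row_permutation_invariance(self):
        df = gaussian_chain(n=800, seed=5)
        sk1 = pc_skeleton(df)
        sk2 = pc_skeleton(df.iloc[np.random.default_rng(1).permutation(len(df))])
        assert np.array_equal(sk1.adjacency, sk2.adjacency)

    def test_sepsets_replayable(self):
        """Every recorded separation set indeed gives a test p > alpha."""
        df, _ = random_dag_data(seed=9)
        sk = pc_skeleton(df, alpha=0.05, max_order=3)
        X = df.to_numpy()
        corr = np.corrcoef(X, rowvar=False)
        n = len(df)
        from lipidnet.network import _fisher_z_p

        for (i, j), S in sk.sepsets.items():
            r = partial_correlation(corr, i, j, tuple(S))
            assert _fisher_z_p(r, n, len(S)) > 0.05

    def test_bad_inputs_rejected(self):
        df = gaussian_chain(n=100)
        with pytest.raises(ValueError):
            pc_skeleton(df, max_order=-1)
        df2 = df.copy()
        df2["X"] = 1.0  # constant -> NaN correlation
        with pytest.raises(ValueError):
            pc_skeleton(df2)


class TestRobustEdges:
    def test_intersection_and_threshold_rules(self):
        rng = np.random.default_rng(3)
        df = gaussian_chain(n=2000, seed=3)
        ska = pc_skeleton(df)
        skb = pc_skeleton(df.iloc[: len(df) // 2])
        # edge present in a only -> dropped
        only_a = ska.edges - skb.edges
        net = robust_edges(ska, skb, df, threshold=0.1)
        kept = {frozenset((a, b)) for a, b, _, _ in net.edges}
        assert kept <= (ska.edges & skb.edges)
        for e in only_a:
            assert e not in kept

    def test_threshold_boundary(self):
        """|pcor| just under the threshold is dropped, just over is kept."""
        rng = np.random.default_rng(8)
        n = 20000
        for rho, expect_kept in [(0.09, False), (0.13, True)]:
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
            df = pd.DataFrame({"x": x, "y": y})
            ska = pc_skeleton(df, alpha=0.05, max_order=0)
            net = robust_edges(ska, ska, df, threshold=0.1)
            assert (len(net.edges) == 1) == expect_kept

    def test_monotone_shrinkage_in_threshold(self, small_blom):
        sk = pc_skeleton(small_blom.values, alpha=0.05, max_order=2)
        sizes = []
        for t in (0.05, 0.1, 0.2, 0.4):
            net = robust_edges(sk, sk, small_blom.values, threshold=t)
            sizes.append(len(net.edges))
        assert sizes == sorted(sizes, reverse=True)

    def test_node_mismatch_rejected(self):
        a = pc_skeleton(gaussian_chain(n=200))
        df = gaussian_chain(n=200).rename(columns={"X": "W"})
        b = pc_skeleton(df)
        with pytest.raises(ValueError):
            robust_edges(a, b, gaussian_chain(n=200))


class TestWalktrap:
    def make_net(self, edges, nodes):
        return LipidNetwork(nodes=nodes, edges=[(a, b, 0.5, True) for a, b in edges])

    def test_two_disjoint_cliques(self):
        nodes = [f"n{i}" for i in range(10)]
        edges = [
            (f"n{i}", f"n{j}")
            for base in (0, 5)
            for i in range(base, base + 5)
            for j in range(i + 1, base + 5)
        ]
        part = walktrap_clusters(self.make_net(edges, nodes))
        assert len(set(part.values())) == 2
        assert len({part[f"n{i}"] for i in range(5)}) == 1
        assert len({part[f"n{i}"] for i in range(5, 10)}) == 1

    def test_single_edge_plus_isolate(self):
        part = walktrap_clusters(self.make_net([("A", "B")], ["A", "B", "C"]))
        assert part["A"] == part["B"] != part["C"]
        assert sorted(set(part.values())) == [1, 2]

    def test_planted_partition_ari(self):
        from sklearn.metrics import adjusted_rand_score
        import igraph as ig

        rng = np.random.default_rng(4)
        blocks, size = 5, 10
        n = blocks * size
        labels = np.repeat(np.arange(blocks), size)
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.8 if labels[i] == labels[j] else 0.02
                if rng.random() < p:
                    edges.append((f"n{i}", f"n{j}"))
        nodes = [f"n{i}" for i in range(n)]
        part = walktrap_clusters(self.make_net(edges, nodes))
        found = [part[f"n{i}"] for i in range(n)]
        assert adjusted_rand_score(labels, found) >= 0.9

    def test_empty_graph_warns_singletons(self):
        net = self.make_net([], ["A", "B"])
        with pytest.warns(UserWarning):
            part = walktrap_clusters(net)
        assert sorted(part.values()) == [1, 2]

    def test_invalid_steps(self):
        with pytest.raises(ValueError):
            walktrap_clusters(self.make_net([("A", "B")], ["A", "B"]), steps=0)


def test_split_half_network_clusters_recover_blocks(small_cohort, small_blom):
    """Split-half robust network groups features from the same generating block."""
    net = split_half_network(small_blom, small_cohort.strata, seed=9)
    truth = small_cohort.truth["cluster_labels"]
    # majority-label purity over non-singleton clusters
    purities, sizes = [], []
    for cid, members in net.cluster_members().items():
        if len(members) < 2:
            continue
        labs = [truth[m] for m in members]
        purities.append(max(labs.count(l) for l in set(labs)) / len(labs))
        sizes.append(len(labs))
    assert purities, "no multi-member clusters found"
    assert np.average(purities, weights=sizes) >= 0.8
    # kept edges are a subset of each half's skeleton by construction:
    # robust edges must connect features of the same or adjacent truth blocks
    assert all(e[3] for e in net.edges)  # all flagged robust
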