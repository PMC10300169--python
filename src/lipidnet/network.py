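"""Conditional-independence lipid network and walktrap clusters.

The skeleton of the PC algorithm is learned from Gaussian (Blom-scaled)
data with Fisher-z partial-correlation tests; edges are kept only when they
appear in two independently learned skeletons (edge stability across two
datasets, here two random halves of the matched strata unless two datasets
are supplied) and their partial correlation exceeds a threshold. Walktrap
community detection on the resulting network yields the lipid clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
from scipy import stats

__all__ = ["Skeleton", "LipidNetwork", "pc_skeleton", "partial_correlation", "robust_edges", "walktrap_clusters", "split_half_network"]


@dataclass
class Skeleton:
    """Undirected PC-algorithm skeleton with the separation sets that
    justified each edge removal (a replayable audit trail)."""

    nodes: list[str]
    adjacency: np.ndarray  # boolean, symmetric
    sepsets: dict[tuple[int, int], tuple[int, ...]]
    n_samples: int
    params: dict = field(default_factory=dict)

    @property
    def edges(self) -> set[frozenset]:
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return {frozenset((self.nodes[a], self.nodes[b])) for a, b in zip(i, j)}

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])


@dataclass
class LipidNetwork:
    """Robust lipid network: nodes, weighted edges and a cluster partition."""

    nodes: list[str]
    edges: list[tuple[str, str, float, bool]]  # (a, b, partial_correlation, robust)
    partition: dict[str, int] = field(default_factory=dict)
    algorithm_params: dict = field(default_factory=dict)

    def graph(self) -> ig.Graph:
        g = ig.Graph()
        g.add_vertices(self.nodes)
        g.add_edges([(a, b) for a, b, _, _ in self.edges])
        g.es["partial_correlation"] = [r for _, _, r, _ in self.edges]
        g.es["robust"] = [rb for _, _, _, rb in self.edges]
        return g

    def cluster_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.partition.items():
            out.setdefault(cid, []).append(node)
        return {cid: sorted(m) for cid, m in sorted(out.items())}


def _fisher_z_p(r: float, n: int, k: int) -> float:
    """Two-sided p-value for partial correlation r given k conditioning vars."""
    dof = n - k - 3
    if dof <= 0:
        return 1.0
    r = float(np.clip(r, -0.999999, 0.999999))
    z = 0.5 * np.log1p(2 * r / (1 - r))
    return 2.0 * stats.norm.sf(np.sqrt(dof) * abs(z))


def partial_correlation(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    """Partial correlation of i and j given S, from the correlation matrix."""
    if not S:
        return float(corr[i, j])
    idx = [i, j, *S]
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub)
    return float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))


def pc_skeleton(
    data,
    alpha: float = 0.05,
    max_order: int = 3,
    feature_names: list[str] | None = None,
) -> Skeleton:
    """PC-stable skeleton with Gaussian conditional-independence tests.

    Starting from the complete graph, for conditioning-set sizes
    l = 0..max_order an edge (i, j) is removed as soon as some
    S subset adj(i)\\{j} (then adj(j)\\{i}) with |S| = l yields a Fisher-z
    partial-correlation test with p > alpha; S is recorded as the separation
    set. Adjacency is frozen at the start of each order level (PC-stable),
    and subsets are enumerated lexicographically over the input column
    order, so the output is deterministic.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    X = np.asarray(getattr(data, "to_numpy", lambda: data)(), dtype=float)
    if feature_names is None:
        feature_names = (
            [str(c) for c in data.columns] if hasattr(data, "columns")
            else [f"v{j}" for j in range(X.shape[1])]
        )
    n, p = X.shape
    corr = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("non-finite correlations (constant feature?)")

    adj = ~np.eye(p, dtype=bool)
    sepsets: dict[tuple[int, int], tuple[int, ...]] = {}

    # order 0: marginal tests, vectorized
    pvals = np.ones((p, p))
    dof = n - 3
    rr = np.clip(corr, -0.999999, 0.999999)
    z = 0.5 * np.log((1 + rr) / (1 - rr))
    pvals = 2.0 * stats.norm.sf(np.sqrt(max(dof, 0)) * np.abs(z))
    for i in range(p):
        for j in range(i + 1, p):
            if pvals[i, j] > alpha:
                adj[i, j] = adj[j, i] = False
                sepsets[(i, j)] = ()

    # Fisher-z critical value: |r| below this cannot reject independence
    crit = {
        order: np.tanh(stats.norm.isf(alpha / 2.0) / np.sqrt(n - order - 3))
        if n - order - 3 > 0
        else np.inf
        for order in range(max_order + 1)
    }

    for order in range(1, max_order + 1):
        adj_snapshot = adj.copy()
        any_tested = False
        for i in range(p):
            for j in range(i + 1, p):
                if not adj[i, j]:
                    continue
                removed = False
                for anchor, other in ((i, j), (j, i)):
                    nbrs = [k for k in np.flatnonzero(adj_snapshot[anchor]) if k != other]
                    if len(nbrs) < order:
                        continue
                    any_tested = True
                    combos = np.array(list(itertools.combinations(nbrs, order)))
                    # batched partial correlations: invert all (2+order)-dim
                    # submatrices at once, lexicographic order preserved
                    idx = np.concatenate(
                        [np.full((len(combos), 1), i), np.full((len(combos), 1), j), combos],
                        axis=1,
                    )
                    sub = corr[idx[:, :, None], idx[:, None, :]]
                    try:
                        prec = np.linalg.inv(sub)
                    except np.linalg.LinAlgError:
                        prec = np.linalg.pinv(sub)
                    r = -prec[:, 0, 1] / np.sqrt(prec[:, 0, 0] * prec[:, 1, 1])
                    hits = np.flatnonzero(np.abs(r) < crit[order])
                    if hits.size:
                        first = int(hits[0])
                        adj[i, j] = adj[j, i] = False
                        sepsets[(i, j)] = tuple(int(k) for k in combos[first])
                        removed = True
                    if removed:
                        break
        if not any_tested:
            break

    return Skeleton(
        nodes=list(feature_names),
        adjacency=adj,
        sepsets=sepsets,
        n_samples=n,
        params={"alpha": alpha, "max_order": max_order},
    )


def robust_edges(
    skel_a: Skeleton,
    skel_b: Skeleton,
    data,
    threshold: float = 0.1,
    max_order: int | None = None,
) -> LipidNetwork:
    """Intersect two skeletons and keep edges with |partial correlation| > threshold.

    The partial correlation of a surviving edge is estimated on the pooled
    data given the union of the two endpoints' neighbors in the intersection
    graph, capped at ``max_order`` conditioning variables (the strongest
    marginal correlates are kept when capping).
    """
    if skel_a.nodes != skel_b.nodes:
        raise ValueError("skeletons have different node sets")
    nodes = skel_a.nodes
    X = np.asarray(getattr(data, "to_numpy", lambda: data)(), dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    if max_order is None:
        max_order = int(skel_a.params.get("max_order", 3))

    inter = skel_a.adjacency & skel_b.adjacency
    p = len(nodes)
    edges: list[tuple[str, str, float, bool]] = []
    for i in range(p):
        for j in range(i + 1, p):
            if not inter[i, j]:
                continue
            nbrs = sorted(set(np.flatnonzero(inter[i])) | set(np.flatnonzero(inter[j])) - {i, j})
            nbrs = [k for k in nbrs if k not in (i, j)]
            if len(nbrs) > max_order:
                strength = np.maximum(np.abs(corr[i, nbrs]), np.abs(corr[j, nbrs]))
                keep = np.argsort(-strength, kind="stable")[:max_order]
                nbrs = [nbrs[k] for k in sorted(keep)]
            r = partial_correlation(corr, i, j, tuple(nbrs))
            if abs(r) > threshold:
                edges.append((nodes[i], nodes[j], r, True))

    return LipidNetwork(
        nodes=list(nodes),
        edges=edges,
        algorithm_params={
            "alpha": skel_a.params.get("alpha"),
            "max_order": max_order,
            "threshold": threshold,
            "conditioning": "union of intersection-skeleton neighbors, capped at max_order",
        },
    )


def walktrap_clusters(network: LipidNetwork, steps: int = 4) -> dict[str, int]:
    """Walktrap community detection; partition ids dense from 1.

    The dendrogram is cut at maximum modularity; isolated nodes fall into
    singleton clusters. Edge weights are |partial correlation|.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    g = network.graph()
    if g.ecount() == 0:
        import warnings

        warnings.warn("empty graph: every node becomes a singleton cluster")
        membership = list(range(g.vcount()))
    else:
        weights = [abs(w) for w in g.es["partial_correlation"]]
        dendro = g.community_walktrap(weights=weights, steps=steps)
        membership = dendro.as_clustering().membership
    # relabel densely from 1, in order of first appearance over input node order
    relabel: dict[int, int] = {}
    partition: dict[str, int] = {}
    for node, m in zip(network.nodes, membership):
        if m not in relabel:
            relabel[m] = len(relabel) + 1
        partition[node] = relabel[m]
    network.partition = partition
    network.algorithm_params["walktrap_steps"] = steps
    return partition


def split_half_network(
    transformed,
    strata,
    *,
    alpha: float = 0.05,
    max_order: int = 3,
    threshold: float = 0.1,
    walktrap_steps: int = 4,
    seed: int = 0,
) -> LipidNetwork:
    """Learn the robust lipid network from two random halves of the strata.

    Stands in for edge stability across two case-control studies when only
    one dataset is available: strata are split at random into two halves, a
    PC skeleton is learned on each, and only edges present in both with
    pooled |partial correlation| > threshold are retained, then clustered
    with walktrap.
    """
    values = transformed.values if hasattr(transformed, "transform_tag") else transformed
    strata = np.asarray(strata)
    uniq = np.unique(strata)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E7]))
    perm = rng.permutation(len(uniq))
    half_a = set(uniq[perm[: len(uniq) // 2]])
    mask_a = np.isin(strata, list(half_a))
    skel_a = pc_skeleton(values[mask_a], alpha=alpha, max_order=max_order)
    skel_b = pc_skeleton(values[~mask_a], alpha=alpha, max_order=max_order)
    net = robust_edges(skel_a, skel_b, values, threshold=threshold, max_order=max_order)
    walktrap_clusters(net, steps=walktrap_steps)
    net.algorithm_params["split_half_seed"] = seed
    return net
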