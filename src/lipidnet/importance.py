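"""Random-forest cluster importance via joint permutation.

A bagged classification forest (default 500 trees, each grown on a 2/3
subsample of rows drawn without replacement) is fitted to the
strata-deviation lipid matrix. For each cluster, every member column is
permuted with one shared row permutation within each tree's out-of-bag rows
(preserving the within-cluster dependence structure) and the increase of the
out-of-bag misclassification rate over baseline is that cluster's
importance; the cluster with the largest increase ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = ["RFParams", "ClusterImportance", "rank_clusters"]


@dataclass
class RFParams:
    n_trees: int = 500
    sample_rate: float = 2.0 / 3.0
    sample_with_replacement: bool = False
    max_features: str | int | float = "sqrt"
    n_permutations: int = 10
    seed: int = 0


@dataclass
class ClusterImportance:
    """Per-cluster OOB error increase under joint permutation, plus ranks."""

    table: pd.DataFrame  # cluster_id, n_features, oob_error_increase, rank
    baseline_oob_error: float
    rf_params: RFParams
    members: dict[int, list[str]] = field(default_factory=dict)

    def top_clusters(self, k: int = 7) -> list[int]:
        t = self.table.sort_values("rank")
        return t["cluster_id"].head(k).tolist()


def _oob_error(vote_case: np.ndarray, vote_total: np.ndarray, y: np.ndarray) -> float:
    """Majority-vote OOB misclassification rate over rows with >= 1 vote;
    exact ties predict the case class."""
    covered = vote_total > 0
    pred = (vote_case[covered] * 2 >= vote_total[covered]).astype(int)
    return float(np.mean(pred != y[covered]))


def rank_clusters(
    deviations,
    outcome: np.ndarray,
    partition: dict[str, int],
    rf_params: RFParams | None = None,
) -> ClusterImportance:
    """Rank lipid clusters by joint-permutation OOB importance.

    ``deviations`` is the strata-deviation matrix (TransformedMatrix or
    DataFrame); ``partition`` maps feature name -> cluster id and must cover
    every column. The permutation is a single shared shuffle of each tree's
    OOB rows applied to all member columns, repeated ``n_permutations``
    times and averaged.
    """
    rf_params = rf_params or RFParams()
    values = deviations.values if hasattr(deviations, "transform_tag") else pd.DataFrame(deviations)
    missing = [c for c in values.columns if c not in partition]
    if missing:
        raise ValueError(f"partition does not cover features: {missing[:5]}")
    y = np.asarray(outcome).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; nothing to predict")
    X = values.to_numpy(dtype=float)
    n = X.shape[0]
    feat_names = list(values.columns)
    cluster_ids = sorted(set(partition[f] for f in feat_names))
    members = {cid: [f for f in feat_names if partition[f] == cid] for cid in cluster_ids}
    for cid, m in members.items():
        if not m:
            raise ValueError(f"cluster {cid} has zero features")
    col_idx = {cid: np.array([feat_names.index(f) for f in members[cid]]) for cid in cluster_ids}

    rng = np.random.default_rng(np.random.SeedSequence([rf_params.seed, 0xF0E5]))
    n_sub = max(1, int(np.floor(rf_params.sample_rate * n)))

    trees = []
    oob_rows = []
    vote_case = np.zeros(n)
    vote_total = np.zeros(n)
    tree_seeds = rng.integers(0, 2**31 - 1, rf_params.n_trees)
    for t in range(rf_params.n_trees):
        if rf_params.sample_with_replacement:
            in_bag = rng.choice(n, n_sub, replace=True)
            oob = np.setdiff1d(np.arange(n), in_bag)
        else:
            permv = rng.permutation(n)
            in_bag, oob = permv[:n_sub], permv[n_sub:]
        tree = DecisionTreeClassifier(max_features=rf_params.max_features, random_state=int(tree_seeds[t]))
        tree.fit(X[in_bag], y[in_bag])
        trees.append(tree)
        oob_rows.append(oob)
        pred = tree.predict(X[oob])
        vote_case[oob] += pred
        vote_total[oob] += 1

    baseline = _oob_error(vote_case, vote_total, y)

    # one permutation RNG per (cluster, repeat, tree), derived from the seed,
    # so repeated evaluation with the same seed is bit-identical; all
    # (cluster, repeat) variants of a tree's OOB block are stacked into one
    # predict call to keep the per-call overhead off the hot path
    n_rep = rf_params.n_permutations
    variants = [(ci, r) for ci in range(len(cluster_ids)) for r in range(n_rep)]
    vc = np.zeros((len(variants), n))
    vt = np.zeros((len(variants), n))
    for t, (tree, oob) in enumerate(zip(trees, oob_rows)):
        m = len(oob)
        if m == 0:
            continue
        big = np.tile(X[oob], (len(variants), 1))
        for v, (ci, r) in enumerate(variants):
            cols = col_idx[cluster_ids[ci]]
            prng = np.random.default_rng(np.random.SeedSequence([rf_params.seed, 7, ci, r, t]))
            block = big[v * m : (v + 1) * m]
            block[:, cols] = block[prng.permutation(m)][:, cols]
        preds = tree.predict(big)
        for v in range(len(variants)):
            vc[v, oob] += preds[v * m : (v + 1) * m]
            vt[v, oob] += 1
    increases = {}
    for ci, cid in enumerate(cluster_ids):
        errs = [
            _oob_error(vc[ci * n_rep + r], vt[ci * n_rep + r], y) for r in range(n_rep)
        ]
        increases[cid] = float(np.mean(errs)) - baseline

    table = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "n_features": [len(members[c]) for c in cluster_ids],
            "oob_error_increase": [increases[c] for c in cluster_ids],
        }
    )
    # rank 1 = largest increase; ties broken by cluster id for determinism
    order = table.sort_values(["oob_error_increase", "cluster_id"], ascending=[False, True])
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    table["rank"] = ranks
    return ClusterImportance(
        table=table, baseline_oob_error=baseline, rf_params=rf_params, members=members
    )
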