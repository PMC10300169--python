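import warnings

import numpy as np
import pandas as pd
import pytest

from lipidnet.cohort import CohortSpec, generate_cohort
from lipidnet.factors import (
    fit_pca_controls,
    project_scores,
    quartile_association,
    varimax,
)
from lipidnet.preprocess import blom_transform


def block_data(n=600, blocks=3, size=10, rho=0.7, seed=8):
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(blocks):
        g = rng.normal(size=(n, 1))
        cols.append(np.sqrt(rho) * g + np.sqrt(1 - rho) * rng.normal(size=(n, size)))
    return pd.DataFrame(np.hstack(cols), columns=[f"f{j}" for j in range(blocks * size)])


def test_identity_correlation_retains_nothing():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(500, 20)))
    with pytest.warns(UserWarning):
        fm = fit_pca_controls(df, np.ones(500, bool))
    assert fm.retained == 0
    np.testing.assert_allclose(fm.eigenvalues, 1.0, atol=0.5)


def test_three_blocks_retained_and_labeled():
    df = block_data()
    fm = fit_pca_controls(df, np.ones(len(df), bool))
    assert fm.retained == 3
    rel = fm.relevant_loadings()
    found_blocks = {tuple(sorted(int(f[1:]) // 10 for f in feats)) for feats in rel.values()}
    assert found_blocks == {(0,) * 10, (1,) * 10, (2,) * 10}
    assert 0.5 < fm.variance_explained < 1.0


def test_varimax_preserves_communalities_and_orthogonality():
    df = block_data(seed=3)
    X = df.to_numpy()
    corr = np.corrcoef(X, rowvar=False)
    eig, vec = np.linalg.eigh(corr)
    order = np.argsort(eig)[::-1]
    L = vec[:, order[:3]] * np.sqrt(eig[order[:3]])
    R = varimax(L)
    np.testing.assert_allclose((L**2).sum(axis=1), (R**2).sum(axis=1), atol=1e-8)
    # rotated loadings stay an orthogonal transform of the original block
    gram_L = L.T @ L
    gram_R = R.T @ R
    assert np.trace(gram_R) == pytest.approx(np.trace(gram_L), abs=1e-8)


def test_varimax_single_factor_identity():
    L = np.arange(5, dtype=float)[:, None]
    np.testing.assert_array_equal(varimax(L), L)


def test_projection_centering_and_linearity():
    df = block_data(seed=4)
    fm = fit_pca_controls(df, np.ones(len(df), bool))
    # a subject at the controls' means scores 0 on every factor
    at_means = pd.DataFrame([fm.control_means], columns=df.columns)
    np.testing.assert_allclose(
        project_scores(fm, at_means).to_numpy(), 0.0, atol=1e-10
    )
    # doubling a feature moves only factors loading on it
    base = df.iloc[[0]]
    bumped = base.copy()
    bumped.iloc[0, 0] = bumped.iloc[0, 0] + 1.0
    delta = (project_scores(fm, bumped) - project_scores(fm, base)).to_numpy().ravel()
    loads = fm.loadings[0] / fm.control_sds[0]
    np.testing.assert_allclose(delta, loads, atol=1e-10)


def test_projection_score_variance_matches_analytic():
    """Control-score variance per factor equals L' Corr L (weighted-sum algebra)."""
    df = block_data(seed=6)
    fm = fit_pca_controls(df, np.ones(len(df), bool))
    scores = project_scores(fm, df)
    Z = (df.to_numpy() - fm.control_means) / fm.control_sds
    corr = np.corrcoef(Z, rowvar=False)
    for k in range(fm.retained):
        analytic = fm.loadings[:, k] @ corr @ fm.loadings[:, k]
        emp = scores.iloc[:, k].var(ddof=1)
        assert emp == pytest.approx(analytic, rel=0.02)


def test_projection_feature_mismatch_rejected():
    df = block_data(seed=5)
    fm = fit_pca_controls(df, np.ones(len(df), bool))
    with pytest.raises(ValueError, match="feature"):
        project_scores(fm, df.rename(columns={"f0": "zzz"}))


@pytest.fixture(scope="module")
def factor_cohort():
    """Cohort whose first generating block carries the signal (members' log-OR 0.4)."""
    spec = CohortSpec(
        n_strata=500, n_lipids=30, n_clusters=3, within_cluster_rho=0.6,
        true_effects={j: 0.4 for j in range(10)}, missing_rate=0.0, seed=23,
    )
    c = generate_cohort(spec)
    blom = blom_transform(c.lipids)
    return c, blom


def test_quartile_association_planted_factor(factor_cohort):
    c, blom = factor_cohort
    fm = fit_pca_controls(blom, c.is_case == 0)
    assert fm.retained >= 1
    scores = project_scores(fm, blom)
    res = quartile_association(c, scores).set_index("factor")
    # the factor aligned with the signal block shows a trend
    signal_factor = None
    rel = fm.relevant_loadings()
    for k, feats in rel.items():
        if sum(int(f.split("_")[1]) < 10 for f in feats) >= 5:
            signal_factor = f"factor_{k}"
    assert signal_factor is not None
    row = res.loc[signal_factor]
    assert row["p_trend"] < 0.05
    top = row["or_q4"]
    assert (top > 1) or (top < 1 and row["or_q2"] < 1)  # monotone direction
    assert np.isfinite(row["p_interaction"])


def test_quartile_cutpoints_depend_only_on_controls(factor_cohort):
    """Perturbing a case's score never moves the cut points: case quartile
    assignments change only via its own value."""
    c, blom = factor_cohort
    fm = fit_pca_controls(blom, c.is_case == 0)
    scores = project_scores(fm, blom)
    s = scores.iloc[:, 0].to_numpy()
    controls = c.is_case == 0
    cuts = np.quantile(s[controls], [0.25, 0.5, 0.75])
    s2 = s.copy()
    s2[~controls] += 10.0  # move all cases far away
    cuts2 = np.quantile(s2[controls], [0.25, 0.5, 0.75])
    np.testing.assert_array_equal(cuts, cuts2)


def test_null_factor_quartile_ors_near_one():
    spec = CohortSpec(n_strata=400, n_lipids=12, n_clusters=2,
                      within_cluster_rho=0.5, missing_rate=0.0, seed=31)
    c = generate_cohort(spec)
    blom = blom_transform(c.lipids)
    fm = fit_pca_controls(blom, c.is_case == 0)
    scores = project_scores(fm, blom)
    res = quartile_association(c, scores)
    ors = res[["or_q2", "or_q3", "or_q4"]].to_numpy().ravel()
    assert np.nanmax(np.abs(np.log(ors))) < 1.0  # no quartile OR wildly off 1
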