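import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from lipidnet.clogit import clogit_fit, wald_test


def brute_force_loglik(X, y, strata, beta):
    """Enumerate the conditional likelihood directly: for each stratum the
    case's exp(eta) over the sum across members."""
    ll = 0.0
    for s in np.unique(strata):
        m = strata == s
        eta = X[m] @ beta
        ll += eta[y[m] == 1][0] - np.log(np.sum(np.exp(eta)))
    return ll


def test_discordant_pair_closed_form(paired_binary):
    X, y, s = paired_binary(6, 3, 4)
    fit = clogit_fit(X, y, s)
    assert fit.converged
    assert fit.coefficients[0] == pytest.approx(np.log(6 / 3), abs=1e-8)
    assert fit.n_informative_strata == 9  # concordant pairs carry nothing


@given(st.integers(1, 30), st.integers(1, 30), st.integers(0, 5))
@settings(max_examples=40, deadline=None)
def test_discordant_pair_closed_form_random_configs(a, b, conc):
    """Coefficient always equals ln(a/b) when both discordant types occur."""
    x, y, s = [], [], []
    sid = 0
    for _ in range(a):
        x += [1.0, 0.0]; y += [1, 0]; s += [sid] * 2; sid += 1
    for _ in range(b):
        x += [0.0, 1.0]; y += [1, 0]; s += [sid] * 2; sid += 1
    for _ in range(conc):
        x += [1.0, 1.0]; y += [1, 0]; s += [sid] * 2; sid += 1
    fit = clogit_fit(np.array(x)[:, None], np.array(y), np.array(s))
    assert fit.coefficients[0] == pytest.approx(np.log(a / b), abs=1e-6)


def test_matches_brute_force_maximizer_small_strata():
    """On <=5 strata of size <=4 the NR maximizer agrees with a direct
    optimization of the enumerated conditional likelihood (configurations
    with an interior maximizer; separated draws are skipped)."""
    checked = 0
    for seed in range(30):
        rng = np.random.default_rng(seed)
        sizes = [2, 3, 4, 4, 3]
        strata = np.repeat(np.arange(5), sizes)
        X = rng.normal(size=(sum(sizes), 2))
        y = np.zeros(sum(sizes), int)
        pos = 0
        for sz in sizes:
            y[pos + rng.integers(sz)] = 1
            pos += sz
        fit = clogit_fit(X, y, strata)
        if not fit.converged or np.linalg.norm(fit.coefficients) > 5:
            continue  # separated draw: no finite maximizer to compare
        res = optimize.minimize(
            lambda b: -brute_force_loglik(X, y, strata, b), np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 5000},
        )
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)
        checked += 1
        if checked >= 5:
            break
    assert checked >= 5


def test_parameter_recovery_on_simulated_cohort():
    rng = np.random.default_rng(11)
    n_strata, size = 1000, 2
    strata = np.repeat(np.arange(n_strata), size)
    X = rng.normal(size=(n_strata * size, 1))
    y = np.zeros(n_strata * size, int)
    for t in range(n_strata):
        lo = size * t
        w = np.exp(0.5 * X[lo : lo + size, 0])
        y[lo + rng.choice(size, p=w / w.sum())] = 1
    fit = clogit_fit(X, y, strata)
    assert abs(fit.coefficients[0] - 0.5) < 0.1


def test_constant_within_stratum_term_dropped(paired_binary):
    X, y, s = paired_binary()
    age = np.repeat(np.arange(13.0), 2)[:, None]  # matched on age: constant per pair
    design = np.hstack([X, age])
    fit = clogit_fit(design, y, s, ["exposure", "age"])
    assert fit.dropped_terms == ["age"]
    assert fit.terms == ["exposure"]


def test_all_concordant_predictor_errors(paired_binary):
    X, y, s = paired_binary(0, 0, 5)  # only concordant pairs
    with pytest.raises(ValueError, match="no informative terms"):
        clogit_fit(X, y, s)


def test_two_case_stratum_rejected():
    X = np.ones((4, 1))
    with pytest.raises(ValueError, match="exactly 1 case"):
        clogit_fit(X, np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1]))


def test_loglik_at_maximum_beats_null(small_cohort, small_blom):
    x = small_blom.values["lipid_000"].to_numpy()[:, None]
    fit = clogit_fit(x, small_cohort.is_case, small_cohort.strata)
    assert fit.loglik >= fit.loglik_null


def test_separation_flagged_not_silent():
    # perfectly separating predictor: case always has larger value
    n = 40
    s = np.repeat(np.arange(n), 2)
    y = np.tile([1, 0], n)
    x = np.where(y == 1, 1.0, 0.0)[:, None] + np.random.default_rng(0).normal(0, 1e-6, (2 * n, 1))
    fit = clogit_fit(x, y, s)
    assert not fit.converged
    assert any("separation" in d for d in fit.diagnostics)


def test_cross_check_statsmodels():
    """Independent oracle: statsmodels ConditionalLogit on the same data."""
    from statsmodels.discrete.conditional_models import ConditionalLogit

    rng = np.random.default_rng(3)
    n_strata = 120
    strata = np.repeat(np.arange(n_strata), 3)
    X = rng.normal(size=(n_strata * 3, 3))
    eta = 0.7 * X[:, 0] - 0.4 * X[:, 1]
    y = np.zeros(n_strata * 3, int)
    for t in range(n_strata):
        lo = 3 * t
        w = np.exp(eta[lo : lo + 3])
        y[lo + rng.choice(3, p=w / w.sum())] = 1
    ours = clogit_fit(X, y, strata)
    ref = ConditionalLogit(y, X, groups=strata).fit(disp=0)
    np.testing.assert_allclose(ours.coefficients, ref.params, atol=2e-4)
    np.testing.assert_allclose(ours.standard_errors, ref.bse, atol=2e-4)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_wald_single_term_identity(small_cohort, small_blom):
    x = small_blom.values["lipid_000"].to_numpy()[:, None]
    fit = clogit_fit(x, small_cohort.is_case, small_cohort.strata, ["lip"])
    w = wald_test(fit, ["lip"])
    assert w["df"] == 1
    assert w["statistic"] == pytest.approx((fit.coef("lip") / fit.se("lip")) ** 2, abs=1e-10)


def test_wald_orthogonal_terms_add():
    """With a (near-)diagonal covariance the joint statistic is the sum of
    the single-term statistics."""
    rng = np.random.default_rng(9)
    n_strata = 400
    strata = np.repeat(np.arange(n_strata), 2)
    X = rng.normal(size=(n_strata * 2, 2))
    eta = 0.4 * X[:, 0] + 0.3 * X[:, 1]
    y = np.zeros(n_strata * 2, int)
    for t in range(n_strata):
        lo = 2 * t
        w = np.exp(eta[lo : lo + 2])
        y[lo + rng.choice(2, p=w / w.sum())] = 1
    fit = clogit_fit(X, y, strata, ["a", "b"])
    # force exact orthogonality for the identity check
    fit.covariance = np.diag(np.diag(fit.covariance))
    fit.standard_errors = np.sqrt(np.diag(fit.covariance))
    joint = wald_test(fit, ["a", "b"])["statistic"]
    single = wald_test(fit, ["a"])["statistic"] + wald_test(fit, ["b"])["statistic"]
    assert joint == pytest.approx(single, rel=1e-10)


def test_wald_zero_coefficient_gives_p_one():
    fit_like = clogit_fit(
        np.array([[1.0], [0.0], [0.0], [1.0]]),
        np.array([1, 0, 1, 0]),
        np.array([0, 0, 1, 1]),
        ["x"],
    )
    # balanced discordance -> coefficient 0
    assert fit_like.coefficients[0] == pytest.approx(0.0, abs=1e-10)
    w = wald_test(fit_like, ["x"])
    assert w["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert w["p"] == pytest.approx(1.0)
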