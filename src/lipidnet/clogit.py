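"""Conditional logistic regression for 1:m matched case-control sets.

The conditional likelihood for stratum s with case i* is

    L_s(beta) = exp(beta' x_{i*}) / sum_{j in s} exp(beta' x_j),

which eliminates stratum-specific intercepts: anything constant within every
stratum (the matching variables) carries no information and is dropped with a
report. The maximizer is found by Newton-Raphson with step-halving on the
exact conditional score and observed information; standard errors come from
the inverse observed information at the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["CLogitFit", "clogit_fit", "wald_test"]

#: coefficient-norm threshold beyond which a non-vanishing gradient is
#: treated as (quasi-)separation rather than slow convergence
_SEPARATION_NORM = 15.0


@dataclass
class CLogitFit:
    """Fitted conditional logistic regression."""

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    covariance: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    n_iter: int
    n_informative_strata: int
    dropped_terms: list[str] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])

    def summary(self) -> dict:
        z = self.coefficients / self.standard_errors
        p = 2.0 * stats.norm.sf(np.abs(z))
        lo = self.coefficients - 1.959963984540054 * self.standard_errors
        hi = self.coefficients + 1.959963984540054 * self.standard_errors
        return {
            t: {
                "coef": float(self.coefficients[k]),
                "se": float(self.standard_errors[k]),
                "or": float(np.exp(self.coefficients[k])),
                "ci_low": float(np.exp(lo[k])),
                "ci_high": float(np.exp(hi[k])),
                "p": float(p[k]),
            }
            for k, t in enumerate(self.terms)
        }


def _prepare(X: np.ndarray, y: np.ndarray, strata: np.ndarray):
    """Sort by stratum, validate composition, center X within strata."""
    order = np.argsort(strata, kind="stable")
    X, y, strata = X[order], y[order], strata[order]
    uniq, starts = np.unique(strata, return_index=True)  # strata is sorted, starts ascending
    case_per = np.add.reduceat(y, starts)
    if not np.all(case_per == 1):
        bad = uniq[case_per != 1]
        raise ValueError(f"every stratum needs exactly 1 case; offending strata: {bad[:5]}")
    sizes = np.diff(np.append(starts, len(y)))
    # center within stratum: shifts constant per stratum cancel in the
    # conditional likelihood, and constant columns become exactly zero
    means = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    Xc = X - np.repeat(means, sizes, axis=0)
    return Xc, y, starts, sizes


def _loglik_parts(Xc, y, starts, sizes, beta):
    eta = Xc @ beta
    # within-stratum log-sum-exp, stable
    emax = np.maximum.reduceat(eta, starts)
    expd = np.exp(eta - np.repeat(emax, sizes))
    denom = np.add.reduceat(expd, starts)
    ll = float(np.sum(eta[y == 1]) - np.sum(emax + np.log(denom)))
    p = expd / np.repeat(denom, sizes)
    return ll, p


def clogit_fit(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    terms: list[str] | None = None,
    *,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> CLogitFit:
    """Fit a conditional logistic regression by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) design matrix (no intercept; it is not identifiable).
    y : (n,) 0/1 case indicators, exactly one case per stratum.
    strata : (n,) matched-set labels.
    terms : column names; defaults to ``x0..x{p-1}``.
    beta0 : optional warm start (on the retained columns, pre-drop order).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    strata = np.asarray(strata)
    if terms is None:
        terms = [f"x{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")

    Xc, ys, starts, sizes = _prepare(X, y, strata)

    # drop terms constant within every stratum
    keep = ~np.all(np.abs(Xc) < 1e-12, axis=0)
    dropped = [t for t, k in zip(terms, keep) if not k]
    kept_terms = [t for t, k in zip(terms, keep) if k]
    diagnostics = []
    if dropped:
        diagnostics.append(f"dropped within-stratum-constant terms: {dropped}")
    Xc = Xc[:, keep]
    p_dim = Xc.shape[1]
    if p_dim == 0:
        raise ValueError("no informative terms remain after dropping matching-constant columns")

    informative = np.add.reduceat((np.abs(Xc) > 1e-12).any(axis=1).astype(float), starts) > 0
    n_informative = int(informative.sum())

    beta = np.zeros(p_dim)
    if beta0 is not None:
        beta0 = np.asarray(beta0, dtype=float)
        beta = beta0[keep] if beta0.shape[0] == len(terms) else beta0.copy()
    ll_null, _ = _loglik_parts(Xc, ys, starts, sizes, np.zeros(p_dim))
    ll, probs = _loglik_parts(Xc, ys, starts, sizes, beta)

    converged = False
    cold_restarted = not np.any(beta)
    it = 0
    for it in range(1, max_iter + 1):
        grad = Xc.T @ (ys - probs)
        # observed information: sum_s [sum_j p_j x_j x_j' - m_s m_s']
        m = np.add.reduceat(probs[:, None] * Xc, starts, axis=0)
        info = (Xc * probs[:, None]).T @ Xc - m.T @ m
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
            diagnostics.append(f"singular information at iteration {it}; least-squares step")
        # step-halving
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, probs_new = _loglik_parts(Xc, ys, starts, sizes, cand)
            if ll_new >= ll - 1e-14:
                break
            scale *= 0.5
        else:
            if not cold_restarted:
                # a bad warm start can make the Newton step a descent
                # direction; restart once from zero
                cold_restarted = True
                beta = np.zeros(p_dim)
                ll, probs = ll_null, _loglik_parts(Xc, ys, starts, sizes, beta)[1]
                continue
            if np.linalg.norm(grad) < 1e-6:
                converged = True  # flat at the optimum; nothing left to gain
            else:
                diagnostics.append("step-halving failed to improve the log-likelihood")
            break
        delta = ll_new - ll
        beta, ll, probs = cand, ll_new, probs_new
        if abs(delta) < tol:
            converged = True
            break

    grad = Xc.T @ (ys - probs)
    if np.linalg.norm(beta) > _SEPARATION_NORM:
        # a diverging coefficient means (quasi-)separation whether the score
        # is still non-zero or the likelihood has already plateaued
        converged = False
        kind = "non-vanishing score" if np.linalg.norm(grad) > 1e-4 else "plateaued likelihood"
        diagnostics.append(
            f"possible separation: |beta|={np.linalg.norm(beta):.1f} with {kind}"
        )

    m = np.add.reduceat(probs[:, None] * Xc, starts, axis=0)
    info = (Xc * probs[:, None]).T @ Xc - m.T @ m
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
        diagnostics.append("singular information at optimum; pseudo-inverse covariance")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return CLogitFit(
        terms=kept_terms,
        coefficients=beta,
        standard_errors=se,
        covariance=cov,
        loglik=ll,
        loglik_null=ll_null,
        converged=converged,
        n_iter=it,
        n_informative_strata=n_informative,
        dropped_terms=dropped,
        diagnostics=diagnostics,
    )


def wald_test(fit: CLogitFit, terms: list[str]) -> dict:
    """Joint Wald chi-square test beta' V^-1 beta for a subset of terms."""
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    idx = [fit.terms.index(t) for t in terms]
    b = fit.coefficients[idx]
    V = fit.covariance[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as e:
        raise ValueError("singular sub-covariance in Wald test") from e
    df = len(idx)
    return {"statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}
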