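"""Varimax-rotated PCA factors of the lipidome and their quartile associations.

PCA runs on the controls' correlation matrix; components with eigenvalue
above a retention threshold (default 2) are kept and varimax-rotated.
Rotated loadings from the controls are applied to all subjects (cases are
projected into the controls' coordinate system), factor scores are cut into
quartiles at the controls' quartile boundaries, and each factor's
association with case status is estimated by conditional logistic
regression (quartile indicators, a quartile-median trend term, and an
intervention-interaction Wald test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clogit import clogit_fit, wald_test
from .screen import build_covariate_design

__all__ = ["FactorModel", "varimax", "fit_pca_controls", "project_scores", "quartile_association"]


@dataclass
class FactorModel:
    feature_names: list[str]
    loadings: np.ndarray  # features x retained factors, varimax-rotated
    eigenvalues: np.ndarray  # all unrotated eigenvalues, descending
    retained: int
    variance_explained: float
    control_means: np.ndarray
    control_sds: np.ndarray
    loading_threshold: float = 0.40

    def relevant_loadings(self) -> dict[int, list[str]]:
        """Factor (1-based) -> features with |loading| above the threshold."""
        out = {}
        for k in range(self.retained):
            mask = np.abs(self.loadings[:, k]) > self.loading_threshold
            out[k + 1] = [f for f, m in zip(self.feature_names, mask) if m]
        return out

    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)


def varimax(loadings: np.ndarray, *, normalize: bool = True, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal; preserves communalities).

    With ``normalize`` (Kaiser normalization) rows are scaled to unit
    communality during rotation, the convention of R's ``varimax``.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    if normalize:
        comm = np.sqrt((L**2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        rotated = L @ R
        tmp = rotated**3 - rotated * (rotated**2).sum(axis=0) / p
        u, s, vt = np.linalg.svd(L.T @ tmp)
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1.0 + tol):
            break
        var = new_var
    out = L @ R
    if normalize:
        out = out * comm[:, None]
    return out


def fit_pca_controls(
    transformed,
    control_mask: np.ndarray,
    *,
    eigenvalue_threshold: float = 2.0,
    loading_threshold: float = 0.40,
) -> FactorModel:
    """PCA of the controls' correlation matrix with eigenvalue-based retention.

    Components with eigenvalue > ``eigenvalue_threshold`` are retained and
    varimax-rotated; variance_explained is the retained eigenvalue sum over
    the number of features.
    """
    values = transformed.values if hasattr(transformed, "transform_tag") else pd.DataFrame(transformed)
    control_mask = np.asarray(control_mask, dtype=bool)
    Xc = values.to_numpy(dtype=float)[control_mask]
    if Xc.shape[0] < 2:
        raise ValueError("need at least 2 controls for PCA")
    means = Xc.mean(axis=0)
    sds = Xc.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [f for f, s in zip(values.columns, sds) if s == 0]
        raise ValueError(f"constant features among controls: {bad[:5]}")
    Z = (Xc - means) / sds
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eig, vec = np.linalg.eigh(corr)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    retained = int(np.sum(eig > eigenvalue_threshold))
    if retained == 0:
        import warnings

        warnings.warn("no eigenvalue exceeds the retention threshold; empty factor model")
        loadings = np.empty((values.shape[1], 0))
    else:
        loadings = vec[:, :retained] * np.sqrt(eig[:retained])
        loadings = varimax(loadings)
    return FactorModel(
        feature_names=[str(c) for c in values.columns],
        loadings=loadings,
        eigenvalues=eig,
        retained=retained,
        variance_explained=float(eig[:retained].sum() / values.shape[1]),
        control_means=means,
        control_sds=sds,
        loading_threshold=loading_threshold,
    )


def project_scores(model: FactorModel, transformed) -> pd.DataFrame:
    """Loading-weighted factor scores for all subjects.

    Features are standardized with the *controls'* means/SDs, then each
    factor score is the loading-weighted sum of standardized features —
    applied identically to cases and controls.
    """
    if model.retained < 1:
        raise ValueError("factor model retains no components")
    values = transformed.values if hasattr(transformed, "transform_tag") else pd.DataFrame(transformed)
    if [str(c) for c in values.columns] != model.feature_names:
        raise ValueError("feature set does not match the factor model")
    Z = (values.to_numpy(dtype=float) - model.control_means) / model.control_sds
    scores = Z @ model.loadings
    return pd.DataFrame(
        scores, index=values.index, columns=[f"factor_{k+1}" for k in range(model.retained)]
    )


def quartile_association(
    cohort,
    factor_scores: pd.DataFrame,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Quartile odds ratios, trend and intervention-interaction per factor.

    Cut points are the controls' score quartiles; ORs contrast quartiles
    2-4 against quartile 1; the trend model replaces the indicators with the
    controls' quartile-specific median score as a single continuous term;
    the interaction adds trend x intervention products (joint 2-df Wald).
    """
    X_cov, cov_names = build_covariate_design(cohort.subjects, covariates)
    y = cohort.is_case
    strata = cohort.strata
    controls = y == 0
    arm = cohort.subjects["intervention"].to_numpy()
    arm_levels = sorted(np.unique(arm))[1:]

    rows = []
    for factor in factor_scores.columns:
        s = factor_scores[factor].to_numpy(dtype=float)
        cuts = np.quantile(s[controls], [0.25, 0.5, 0.75])
        q = np.searchsorted(cuts, s, side="right") + 1  # quartile 1..4
        medians = {k: float(np.median(s[controls & (q == k)])) for k in (1, 2, 3, 4)}

        res: dict = {"factor": factor}
        # quartile-indicator model
        ind = np.column_stack([(q == k).astype(float) for k in (2, 3, 4)])
        terms = [f"q{k}" for k in (2, 3, 4)] + cov_names
        design = np.column_stack([ind, X_cov]) if X_cov.shape[1] else ind
        try:
            fit = clogit_fit(design, y, strata, terms)
            summ = fit.summary()
            for k in (2, 3, 4):
                t = f"q{k}"
                if t in summ:
                    res[f"or_q{k}"] = summ[t]["or"]
                    res[f"ci_low_q{k}"] = summ[t]["ci_low"]
                    res[f"ci_high_q{k}"] = summ[t]["ci_high"]
                    res[f"p_q{k}"] = summ[t]["p"]
                else:  # non-estimable contrast (e.g. empty quartile among cases)
                    res[f"or_q{k}"] = np.nan
        except ValueError as e:
            res["flags"] = f"quartile model: {e}"

        # trend model: per-quartile control medians as one continuous term
        trend = np.vectorize(medians.get)(q).astype(float)
        tdesign = np.column_stack([trend, X_cov]) if X_cov.shape[1] else trend[:, None]
        try:
            tfit = clogit_fit(tdesign, y, strata, ["trend"] + cov_names)
            res["p_trend"] = tfit.summary()["trend"]["p"]
        except ValueError as e:
            res["flags"] = res.get("flags", "") + f"; trend model: {e}"
            res["p_trend"] = np.nan

        # interaction: trend x intervention products, joint Wald
        inter = [trend * (arm == lev) for lev in arm_levels]
        inames = [f"trend_x_intervention_{lev}" for lev in arm_levels]
        idesign = np.column_stack([tdesign] + [c[:, None] for c in inter])
        try:
            ifit = clogit_fit(idesign, y, strata, ["trend"] + cov_names + inames)
            res["p_interaction"] = wald_test(ifit, inames)["p"]
        except ValueError:
            res["p_interaction"] = np.nan
        rows.append(res)

    return pd.DataFrame(rows)
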