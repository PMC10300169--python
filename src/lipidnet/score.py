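"""Elastic-net predictor selection and the LOOCV-weighted multilipid score.

Selection runs in two passes over the strata-deviation data: a tenfold
cross-validated elastic-net logistic regression within each top-ranked
cluster, then a second elastic net over all within-cluster survivors to
obtain the mutually independent predictors. The multilipid score is then
built with leave-one-stratum-out conditional logistic regression: each
matched set is scored with coefficients fitted on all other strata, which
prevents a subject's own outcome from shaping its weights; the final
association is the conditional-logistic odds ratio per SD of the score,
adjusted for the configured covariates, with an intervention-interaction
Wald test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .clogit import CLogitFit, clogit_fit, wald_test
from .screen import build_covariate_design

__all__ = [
    "CVParams",
    "SelectionResult",
    "ScoreModel",
    "enet_within_clusters",
    "enet_across_clusters",
    "build_loocv_score",
]


@dataclass
class CVParams:
    folds: int = 10
    l1_ratios: tuple[float, ...] = (0.1, 0.5, 0.9)
    n_penalties: int = 20
    seed: int = 0


@dataclass
class SelectionResult:
    within_cluster_selected: dict[int, list[str]]
    across_cluster_selected: list[str]
    enet_coefficients: dict[str, float]
    cv_params: CVParams


@dataclass
class ScoreModel:
    """Leave-one-stratum-out weighted multilipid score and its association."""

    selected: list[str]
    weights_per_fold: dict  # left-out stratum -> feature weight vector
    weight_medians: dict[str, float]
    subject_scores: pd.Series
    or_per_sd: float
    ci95: tuple[float, float]
    p: float
    interaction_wald: dict
    n_failed_folds: int = 0
    fit: CLogitFit | None = None


def _enet_select(X: np.ndarray, y: np.ndarray, names: list[str], cv: CVParams):
    """Nonzero-coefficient selection by tenfold CV elastic-net logistic
    regression (deviance loss); features are standardized for the penalty."""
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    folds = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    model = LogisticRegressionCV(
        solver="saga",
        l1_ratios=list(cv.l1_ratios),
        Cs=cv.n_penalties,
        cv=folds,
        scoring="neg_log_loss",
        max_iter=10000,
        tol=1e-5,
        random_state=cv.seed,
        use_legacy_attributes=False,
    )
    model.fit(Xs, y)
    coefs = model.coef_.ravel() / scaler.scale_  # back to the input scale
    sel = {names[j]: float(coefs[j]) for j in np.flatnonzero(np.abs(model.coef_.ravel()) > 1e-8)}
    return sel


def enet_within_clusters(
    deviations,
    outcome: np.ndarray,
    partition: dict[str, int],
    top_clusters: list[int],
    cv_params: CVParams | None = None,
) -> dict[int, list[str]]:
    """Per top cluster, select members with nonzero CV elastic-net coefficients."""
    cv = cv_params or CVParams()
    values = deviations.values if hasattr(deviations, "transform_tag") else pd.DataFrame(deviations)
    y = np.asarray(outcome).astype(int)
    out: dict[int, list[str]] = {}
    for cid in top_clusters:
        feats = [f for f in values.columns if partition[f] == cid]
        if not feats:
            raise ValueError(f"top cluster {cid} has no features")
        sel = _enet_select(values[feats].to_numpy(dtype=float), y, feats, cv)
        out[cid] = sorted(sel, key=feats.index)
    return out


def enet_across_clusters(
    deviations,
    outcome: np.ndarray,
    candidates: dict[int, list[str]] | list[str],
    cv_params: CVParams | None = None,
) -> SelectionResult:
    """Second-pass elastic net over all within-cluster survivors."""
    cv = cv_params or CVParams()
    values = deviations.values if hasattr(deviations, "transform_tag") else pd.DataFrame(deviations)
    if isinstance(candidates, dict):
        within = {int(k): list(v) for k, v in candidates.items()}
        pooled = [f for feats in within.values() for f in feats]
    else:
        within = {0: list(candidates)}
        pooled = list(candidates)
    if not pooled:
        import warnings

        warnings.warn("no candidate features: empty selection")
        return SelectionResult(within, [], {}, cv)
    y = np.asarray(outcome).astype(int)
    sel = _enet_select(values[pooled].to_numpy(dtype=float), y, pooled, cv)
    selected = sorted(sel, key=pooled.index)
    return SelectionResult(within, selected, sel, cv)


def build_loocv_score(
    cohort,
    transformed,
    selected: list[str],
    covariates: list[str] | None = None,
) -> ScoreModel:
    """Build the leave-one-stratum-out weighted multilipid score.

    For each matched set s, a conditional logistic regression on the
    selected (Blom-scaled) lipids plus covariates is fitted on every stratum
    except s; subjects in s are scored as the dot product of their lipid
    values with the held-out coefficient vector. The pooled scores are
    standardized to unit SD and their association with case status is
    estimated by conditional logistic regression with the same covariates;
    the score x intervention interaction is a joint 2-df Wald test.
    """
    if not selected:
        raise ValueError("no selected features; cannot build a score")
    values = transformed.values if hasattr(transformed, "transform_tag") else pd.DataFrame(transformed)
    X_lip = values[selected].to_numpy(dtype=float)
    X_cov, cov_names = build_covariate_design(cohort.subjects, covariates)
    terms = list(selected) + cov_names
    design = np.column_stack([X_lip, X_cov]) if X_cov.shape[1] else X_lip
    y = cohort.is_case
    strata = cohort.strata

    full_fit = clogit_fit(design, y, strata, terms)
    warm = np.zeros(len(terms))
    full_map = dict(zip(full_fit.terms, full_fit.coefficients))
    warm[:] = [full_map.get(t, 0.0) for t in terms]

    uniq = np.unique(strata)
    scores = np.full(len(y), np.nan)
    weights_per_fold: dict = {}
    n_failed = 0
    for s in uniq:
        mask = strata != s
        try:
            fit = clogit_fit(design[mask], y[mask], strata[mask], terms, beta0=warm)
        except ValueError:
            fit = None
        if fit is None or not fit.converged:
            n_failed += 1
            continue
        fmap = dict(zip(fit.terms, fit.coefficients))
        w = np.array([fmap.get(f, 0.0) for f in selected])
        weights_per_fold[s] = w
        rows = np.flatnonzero(strata == s)
        scores[rows] = X_lip[rows] @ w

    scored = np.isfinite(scores)
    if scored.sum() == 0:
        raise ValueError("all leave-one-stratum-out fits failed")
    weight_medians = {
        f: float(np.median([w[k] for w in weights_per_fold.values()]))
        for k, f in enumerate(selected)
    }

    sd = float(np.std(scores[scored], ddof=1))
    z = (scores - np.nanmean(scores)) / sd

    # final association on scored strata only
    keep = scored
    final_terms = ["lipid_score"] + cov_names
    final_design = (
        np.column_stack([z[keep], X_cov[keep]]) if X_cov.shape[1] else z[keep, None]
    )
    final = clogit_fit(final_design, y[keep], strata[keep], final_terms)
    s = final.summary()["lipid_score"]

    # interaction with the 3-arm intervention: 2 product terms, joint Wald
    arm = cohort.subjects["intervention"].to_numpy()
    inter_cols = [z * (arm == lev) for lev in sorted(np.unique(arm))[1:]]
    inter_names = [f"lipid_score_x_intervention_{lev}" for lev in sorted(np.unique(arm))[1:]]
    int_design = np.column_stack([final_design] + [c[keep, None] for c in inter_cols])
    int_fit = clogit_fit(int_design, y[keep], strata[keep], final_terms + inter_names)
    try:
        interaction = wald_test(int_fit, inter_names)
    except ValueError as e:
        interaction = {"statistic": np.nan, "df": len(inter_names), "p": np.nan, "error": str(e)}

    return ScoreModel(
        selected=list(selected),
        weights_per_fold=weights_per_fold,
        weight_medians=weight_medians,
        subject_scores=pd.Series(z, index=cohort.subjects["subject_id"].to_numpy(), name="lipid_score"),
        or_per_sd=s["or"],
        ci95=(s["ci_low"], s["ci_high"]),
        p=s["p"],
        interaction_wald=interaction,
        n_failed_folds=n_failed,
        fit=final,
    )
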