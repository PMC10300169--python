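"""Per-lipid conditional-logistic association screen with BY adjustment.

One conditional logistic regression per lipid (Blom-scaled, so the reported
odds ratio is per SD), adjusted for the configured risk-factor covariates;
raw two-sided Wald p-values are adjusted with the Benjamini-Yekutieli
procedure, which controls the FDR under arbitrary dependence by inflating
the Benjamini-Hochberg thresholds with c(m) = sum_{i<=m} 1/i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clogit import CLogitFit, clogit_fit

__all__ = [
    "DEFAULT_COVARIATES",
    "ScreenResult",
    "build_covariate_design",
    "by_adjust",
    "screen_lipids",
]

#: adjustment covariates of the per-lipid models; recruitment center and sex
#: are matching variables and are dropped automatically (logged) because they
#: are constant within matched strata
DEFAULT_COVARIATES = [
    "center",
    "age",
    "sex",
    "smoking",
    "bmi",
    "diabetes",
    "hypertension",
    "family_history",
    "physical_activity",
    "education",
    "statin",
    "intervention",
]

#: 3-category covariates expanded to indicator sets (reference = category 0)
CATEGORICAL = {"smoking": 3, "education": 3, "intervention": 3, "center": None}


@dataclass
class ScreenResult:
    """Per-feature screen table plus fit diagnostics."""

    table: pd.DataFrame  # feature, or_per_sd, ci_low, ci_high, p_raw, p_by, n_informative_strata, flags
    n_features: int
    family_size: int

    def nominal(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_raw"] < alpha]


def build_covariate_design(
    subjects: pd.DataFrame, covariates: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Expand the covariate list into a numeric design matrix.

    Three-level categoricals (smoking, education, intervention) become two
    indicators against the first category; center becomes indicators over its
    observed levels.
    """
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in covariates:
        if cov not in subjects.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        if cov in CATEGORICAL:
            vals = subjects[cov]
            levels = sorted(vals.unique())
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
                names.append(f"{cov}_{lev}")
        else:
            cols.append(subjects[cov].to_numpy(dtype=float))
            names.append(cov)
    if not cols:
        return np.empty((len(subjects), 0)), []
    return np.column_stack(cols), names


def by_adjust(p: np.ndarray, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values.

    ``family_size`` may exceed the number of finite p-values (failed fits
    still count toward the family); NaN entries propagate as NaN.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    m = int(family_size) if family_size is not None else int(finite.sum())
    if m < int(finite.sum()):
        raise ValueError("family_size smaller than the number of observed p-values")
    out = np.full(p.shape, np.nan)
    pv = p[finite]
    if pv.size == 0:
        return out
    order = np.argsort(pv, kind="stable")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    ranked = pv[order] * m * c_m / np.arange(1, pv.size + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out_f = np.empty(pv.size)
    out_f[order] = np.minimum(adj, 1.0)
    out[finite] = out_f
    return out


def screen_lipids(
    cohort,
    transformed,
    covariates: list[str] | None = None,
    *,
    count_failures_in_family: bool = True,
) -> ScreenResult:
    """Run the per-lipid conditional logistic screen.

    ``transformed`` is the Blom-scaled matrix (a :class:`TransformedMatrix`
    or DataFrame) aligned row-wise with ``cohort.subjects``. Per-feature fit
    failures are reported with missing p-values and never abort the screen.
    """
    values = transformed.values if hasattr(transformed, "values") and hasattr(transformed, "transform_tag") else pd.DataFrame(transformed)
    X_cov, cov_names = build_covariate_design(cohort.subjects, covariates)
    y = cohort.is_case
    strata = cohort.strata

    rows = []
    beta_warm: np.ndarray | None = None
    for feat in values.columns:
        x = values[feat].to_numpy(dtype=float)
        design = np.column_stack([x, X_cov]) if X_cov.shape[1] else x[:, None]
        terms = [str(feat)] + cov_names
        flags = ""
        try:
            fit = clogit_fit(design, y, strata, terms, beta0=beta_warm)
            if beta_warm is None and fit.converged:
                # warm-start subsequent lipid fits from this one's covariate block
                beta_warm = np.zeros(len(terms))
                full = dict(zip(fit.terms, fit.coefficients))
                beta_warm[1:] = [full.get(t, 0.0) for t in cov_names]
            if not fit.converged:
                flags = ";".join(fit.diagnostics) or "not converged"
                rows.append((feat, *[np.nan] * 4, fit.n_informative_strata, flags))
                continue
            s = fit.summary()[str(feat)]
            rows.append(
                (feat, s["or"], s["ci_low"], s["ci_high"], s["p"], fit.n_informative_strata, flags)
            )
        except ValueError as e:
            rows.append((feat, *[np.nan] * 4, 0, f"error: {e}"))

    table = pd.DataFrame(
        rows,
        columns=["feature", "or_per_sd", "ci_low", "ci_high", "p_raw", "n_informative_strata", "flags"],
    )
    family = len(table) if count_failures_in_family else int(np.isfinite(table["p_raw"]).sum())
    table["p_by"] = by_adjust(table["p_raw"].to_numpy(), family_size=family)
    table = table[
        ["feature", "or_per_sd", "ci_low", "ci_high", "p_raw", "p_by", "n_informative_strata", "flags"]
    ]
    return ScreenResult(table=table, n_features=len(table), family_size=family)
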