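"""Value-level preprocessing for matched lipidomics data.

Three transforms, applied in this order in the pipeline:

1. half-minimum imputation (missing entries of a feature are set to half of
   its minimum detected value, the standard left-censoring assumption for
   LC-MS abundances);
2. Blom's rank-based inverse normal transformation, which maps each feature
   to an approximately standard-normal, SD-scaled variable;
3. matching-strata mean deviations (for the random-forest stage), which
   remove the stratum means so pooled tree fitting respects the matched
   design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TransformedMatrix", "impute_half_min", "blom_transform", "strata_deviation"]


@dataclass
class TransformedMatrix:
    """A subjects x features matrix plus the ordered list of applied transforms."""

    values: pd.DataFrame
    transform_tag: str
    provenance: list[str] = field(default_factory=list)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, TransformedMatrix):
        return matrix.values
    return pd.DataFrame(matrix)


def _provenance(matrix) -> list[str]:
    return list(matrix.provenance) if isinstance(matrix, TransformedMatrix) else ["raw"]


def impute_half_min(matrix) -> TransformedMatrix:
    """Replace every missing entry of feature j with (min observed of j) / 2."""
    df = _as_frame(matrix).copy()
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing) > 0:
        raise ValueError(f"features entirely missing, cannot impute: {list(all_missing)}")
    fills = df.min(axis=0, skipna=True) / 2.0
    df = df.fillna(fills)
    return TransformedMatrix(df, "half_min_imputed", _provenance(matrix) + ["half_min_imputed"])


def blom_transform(matrix) -> TransformedMatrix:
    """Blom rank-based inverse normal transform, per feature.

    value_i = Phi^-1((r_i - 3/8) / (n + 1/4)) with tie-averaged ranks r_i.
    Output is approximately standard normal, so downstream odds ratios are
    per SD of the feature.
    """
    df = _as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("blom_transform requires a complete matrix; impute first")
    x = df.to_numpy(dtype=float)
    constant = df.columns[(x == x[0, :]).all(axis=0)]
    if len(constant) > 0:
        raise ValueError(f"constant features have degenerate ranks: {list(constant)}")
    n = x.shape[0]
    ranks = stats.rankdata(x, axis=0, method="average")
    out = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return TransformedMatrix(
        pd.DataFrame(out, index=df.index, columns=df.columns),
        "blom",
        _provenance(matrix) + ["blom"],
    )


def strata_deviation(matrix, strata) -> TransformedMatrix:
    """Subtract matching-stratum means per feature.

    Within every stratum each feature then sums to zero; singleton strata are
    rejected because their deviations are identically zero and carry no
    information.
    """
    df = _as_frame(matrix)
    strata = np.asarray(strata)
    if len(strata) != len(df):
        raise ValueError("stratum labels must cover all rows")
    counts = pd.Series(strata).value_counts()
    singletons = counts.index[counts == 1].tolist()
    if singletons:
        raise ValueError(f"singleton strata carry no within-stratum information: {singletons[:5]}")
    centered = df - df.groupby(strata).transform("mean").to_numpy()
    return TransformedMatrix(centered, "strata_deviation", _provenance(matrix) + ["strata_deviation"])
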