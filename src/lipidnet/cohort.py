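"""Synthetic matched case-control lipidomics cohorts with known ground truth.

The generator emulates a nested case-control design: 1 case plus 1-3 controls
per matched stratum, matching on recruitment center, birth year (+/- 5 years)
and sex; lipid abundances are log-normal with a block (cluster) correlation
structure; case status is assigned within each stratum by conditional-logit
sampling so that downstream conditional logistic regression is correctly
specified and parameter recovery is a clean test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "MatchedCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "composite_effect_sd",
    "scale_effects_to_composite",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "stratum_id",
    "is_case",
    "center",
    "age",
    "sex",
    "bmi",
    "smoking",
    "diabetes",
    "hypertension",
    "family_history",
    "physical_activity",
    "education",
    "statin",
    "intervention",
]

#: default per-stratum distribution of the number of matched controls,
#: chosen so that 512 strata give ~1247 subjects (512 cases + ~735 controls)
DEFAULT_CONTROL_PROBS = (0.60, 0.36, 0.04)


@dataclass
class CohortSpec:
    """Parameters of a synthetic matched cohort.

    ``controls_per_case`` is either a fixed integer in {1, 2, 3} or the
    string ``"draw"``, in which case each stratum draws its control count
    from {1, 2, 3} with probabilities ``control_probs``.

    ``true_effects`` maps lipid column index -> log-odds per SD of the
    latent (standard-normal) lipid level; ``covariate_effects`` maps a
    subject-table column name -> log-odds per unit.
    """

    n_strata: int = 512
    controls_per_case: int | str = "draw"
    control_probs: tuple[float, float, float] = DEFAULT_CONTROL_PROBS
    n_lipids: int = 216
    n_clusters: int = 12
    within_cluster_rho: float = 0.5
    between_cluster_rho: float = 0.0
    true_effects: Mapping[int, float] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    missing_rate: float = 0.02
    censor_mode: str = "left_censor"
    n_centers: int = 5
    allow_control_reuse: bool = False
    control_reuse_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_lipids >= self.n_clusters >= 1):
            raise ValueError(
                f"need n_lipids >= n_clusters >= 1, got {self.n_lipids}, {self.n_clusters}"
            )
        if isinstance(self.controls_per_case, int) and self.controls_per_case not in (1, 2, 3):
            raise ValueError("controls_per_case must be 1, 2, 3 or 'draw'")
        if not 0.0 <= self.within_cluster_rho < 1.0:
            raise ValueError("within_cluster_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if self.censor_mode not in ("left_censor", "MCAR"):
            raise ValueError(f"unknown censor_mode {self.censor_mode!r}")
        for j in self.true_effects:
            if not 0 <= int(j) < self.n_lipids:
                raise ValueError(f"true_effects references invalid lipid index {j}")
        # positive definiteness is verified constructively via Cholesky
        np.linalg.cholesky(_block_correlation(self))

    def spec_hash(self) -> str:
        payload = asdict(self)
        payload["true_effects"] = {str(k): v for k, v in self.true_effects.items()}
        payload["covariate_effects"] = dict(self.covariate_effects)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


@dataclass
class MatchedCohort:
    """A subject table plus lipid abundance matrix, row-aligned.

    ``lipids`` holds nonnegative abundances with NaN for missing entries;
    ``truth`` (optional) records the generating cluster assignment and
    effect maps, and is absent when a cohort is read from real data.
    """

    subjects: pd.DataFrame
    lipids: pd.DataFrame
    truth: dict | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.lipids.columns)

    @property
    def strata(self) -> np.ndarray:
        return self.subjects["stratum_id"].to_numpy()

    @property
    def is_case(self) -> np.ndarray:
        return self.subjects["is_case"].to_numpy().astype(int)

    def validate(self) -> None:
        validate_subject_table(self.subjects)
        if len(self.subjects) != len(self.lipids):
            raise ValueError("subject table and lipid matrix row counts differ")
        if not (self.subjects["subject_id"].to_numpy() == self.lipids.index.to_numpy()).all():
            raise ValueError("lipid matrix row order does not match the subject table")


def validate_subject_table(subjects: pd.DataFrame) -> None:
    """Check stratum composition and matching invariants, with row-level diagnostics."""
    missing = [c for c in SUBJECT_COLUMNS if c not in subjects.columns]
    if missing:
        raise ValueError(f"subject table is missing columns: {missing}")
    if subjects["subject_id"].duplicated().any():
        dupes = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes[:5]}")
    for sid, grp in subjects.groupby("stratum_id"):
        n_cases = int(grp["is_case"].sum())
        n_controls = len(grp) - n_cases
        if n_cases != 1 or not 1 <= n_controls <= 3:
            raise ValueError(
                f"stratum {sid!r} has {n_cases} cases and {n_controls} controls "
                "(needs exactly 1 case and 1-3 controls)"
            )
        if grp["sex"].nunique() > 1:
            raise ValueError(f"stratum {sid!r} mixes sexes")
        if grp["center"].nunique() > 1:
            raise ValueError(f"stratum {sid!r} mixes recruitment centers")
        if grp["age"].max() - grp["age"].min() > 5.0 + 1e-9:
            raise ValueError(f"stratum {sid!r} has age span > 5 years")


def _cluster_sizes(n_lipids: int, n_clusters: int) -> np.ndarray:
    base = n_lipids // n_clusters
    sizes = np.full(n_clusters, base, dtype=int)
    sizes[: n_lipids - base * n_clusters] += 1
    return sizes


def cluster_labels(spec: CohortSpec) -> np.ndarray:
    """Generating cluster label (0-based) per lipid column, contiguous blocks."""
    return np.repeat(np.arange(spec.n_clusters), _cluster_sizes(spec.n_lipids, spec.n_clusters))


def _block_correlation(spec: CohortSpec) -> np.ndarray:
    labels = cluster_labels(spec)
    same = labels[:, None] == labels[None, :]
    sigma = np.where(same, spec.within_cluster_rho, spec.between_cluster_rho)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def composite_effect_sd(spec: CohortSpec) -> float:
    """SD of the generating lipid score sum_j beta_j Z_j (log-odds per SD of that score)."""
    if not spec.true_effects:
        return 0.0
    beta = np.zeros(spec.n_lipids)
    for j, b in spec.true_effects.items():
        beta[int(j)] = b
    sigma = _block_correlation(spec)
    return float(np.sqrt(beta @ sigma @ beta))


def scale_effects_to_composite(
    spec: CohortSpec, target_sd: float
) -> dict[int, float]:
    """Rescale ``spec.true_effects`` so the generating score has SD ``target_sd``."""
    current = composite_effect_sd(spec)
    if current == 0.0:
        raise ValueError("spec has no true effects to scale")
    f = target_sd / current
    return {int(j): b * f for j, b in spec.true_effects.items()}


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Subject-level risk-factor covariates, marginals matched to an elderly
    high-cardiovascular-risk trial population."""
    return pd.DataFrame(
        {
            "bmi": np.round(rng.normal(30.0, 3.8, n), 1),
            "smoking": rng.choice(3, n, p=[0.58, 0.135, 0.285]),
            "diabetes": rng.binomial(1, 0.49, n),
            "hypertension": rng.binomial(1, 0.84, n),
            "family_history": rng.binomial(1, 0.19, n),
            "physical_activity": np.round(rng.gamma(1.1, 208.0, n), 1),
            "education": rng.choice(3, n, p=[0.78, 0.16, 0.06]),
            "statin": rng.binomial(1, 0.36, n),
            "intervention": rng.choice(3, n, p=[0.36, 0.34, 0.30]),
        }
    )


def generate_cohort(spec: CohortSpec) -> MatchedCohort:
    """Generate a matched case-control cohort with known ground truth.

    Lipids are drawn from a block-correlated multivariate normal on the log
    scale (clusters = blocks) and exponentiated to the abundance scale.
    Within each stratum the case is sampled with probability proportional to
    exp(linear predictor), the conditional-logistic data-generating rule.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x10C0]))

    # stratum sizes
    if spec.controls_per_case == "draw":
        n_controls = rng.choice([1, 2, 3], spec.n_strata, p=list(spec.control_probs))
    else:
        n_controls = np.full(spec.n_strata, int(spec.controls_per_case))
    sizes = n_controls + 1
    n = int(sizes.sum())
    stratum_id = np.repeat(np.arange(spec.n_strata), sizes)

    # matching variables are constant within stratum
    center = np.repeat(rng.integers(0, spec.n_centers, spec.n_strata), sizes)
    sex = np.repeat(rng.binomial(1, 0.49, spec.n_strata), sizes)
    base_age = np.repeat(np.clip(rng.normal(68.5, 6.0, spec.n_strata), 57.5, 77.5), sizes)
    # jitter capped at 2.45 so rounding to 0.1 years cannot push the
    # within-stratum age span past the 5-year matching window
    age = np.round(base_age + rng.uniform(-2.45, 2.45, n), 1)

    subjects = _draw_covariates(rng, n)
    subjects.insert(0, "subject_id", [f"S{i:05d}" for i in range(n)])
    subjects.insert(1, "stratum_id", stratum_id)
    subjects.insert(2, "is_case", 0)
    subjects.insert(3, "center", center)
    subjects.insert(4, "age", age)
    subjects.insert(5, "sex", sex)

    # latent standard-normal lipid levels with block correlation
    chol = np.linalg.cholesky(_block_correlation(spec))
    z = rng.standard_normal((n, spec.n_lipids)) @ chol.T

    # optional incidence-density-style control reuse: a member of a later
    # stratum duplicates the covariates and lipid levels of a compatible
    # earlier subject (same center and sex, age within the stratum window);
    # applied before case sampling so the conditional-logit rule stays exact
    reused: dict[str, str] = {}
    if spec.allow_control_reuse and spec.control_reuse_rate > 0:
        cov_cols = [c for c in subjects.columns if c not in ("subject_id", "stratum_id", "is_case")]
        for s in range(1, spec.n_strata):
            lo, hi = int(np.cumsum(np.concatenate([[0], sizes]))[s]), int(np.cumsum(sizes)[s])
            pool = np.flatnonzero(
                (stratum_id < s)
                & (center == center[lo])
                & (sex == sex[lo])
                & (np.abs(age - base_age[lo]) <= 2.45)
            )
            if pool.size == 0:
                continue
            for i in range(lo + 1, hi):  # keep at least one fresh member per stratum
                if rng.random() < spec.control_reuse_rate:
                    donor = int(rng.choice(pool))
                    subjects.loc[i, cov_cols] = subjects.loc[donor, cov_cols]
                    z[i, :] = z[donor, :]
                    age[i] = age[donor]  # keep the array view in sync for later donor pools
                    reused[f"S{i:05d}"] = f"S{donor:05d}"

    # linear predictor: lipid effects act on the latent SD scale
    eta = np.zeros(n)
    for j, b in spec.true_effects.items():
        eta += b * z[:, int(j)]
    for cov, b in spec.covariate_effects.items():
        eta += b * subjects[cov].to_numpy(dtype=float)

    # within-stratum conditional-logit case sampling
    is_case = np.zeros(n, dtype=int)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for s in range(spec.n_strata):
        lo, hi = offsets[s], offsets[s + 1]
        w = np.exp(eta[lo:hi] - eta[lo:hi].max())
        is_case[lo + rng.choice(hi - lo, p=w / w.sum())] = 1
    subjects["is_case"] = is_case

    # abundances: log-normal, feature-specific location/scale
    log_mu = rng.normal(2.0, 0.5, spec.n_lipids)
    log_sd = rng.uniform(0.25, 0.6, spec.n_lipids)
    abund = np.exp(log_mu + log_sd * z)

    # missingness
    if spec.missing_rate > 0:
        if spec.censor_mode == "left_censor":
            k = int(np.floor(spec.missing_rate * n))
            if k > 0:
                order = np.argsort(abund, axis=0)
                abund[order[:k, :], np.arange(spec.n_lipids)[None, :]] = np.nan
        else:  # MCAR
            mask = rng.random((n, spec.n_lipids)) < spec.missing_rate
            abund[mask] = np.nan

    names = [f"lipid_{j:03d}" for j in range(spec.n_lipids)]
    lipids = pd.DataFrame(abund, columns=names, index=subjects["subject_id"].to_numpy())
    lipids.index.name = "subject_id"

    truth = {
        "cluster_labels": {names[j]: int(c) for j, c in enumerate(cluster_labels(spec))},
        "true_effects": {names[int(j)]: float(b) for j, b in spec.true_effects.items()},
        "covariate_effects": dict(spec.covariate_effects),
        "composite_effect_sd": composite_effect_sd(spec),
        "reused_controls": reused,
        "seed": spec.seed,
        "spec_hash": spec.spec_hash(),
    }
    cohort = MatchedCohort(subjects=subjects, lipids=lipids, truth=truth)
    cohort.validate()
    return cohort


def write_cohort(cohort: MatchedCohort, path: str | Path) -> dict[str, Path]:
    """Write subjects.csv, lipids.csv, a truth.json sidecar (if ground truth is
    known) and a manifest; real-data runs simply lack the sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "subjects": path / "subjects.csv",
        "lipids": path / "lipids.csv",
    }
    cohort.subjects.to_csv(files["subjects"], index=False)
    cohort.lipids.to_csv(files["lipids"], na_rep="")
    if cohort.truth is not None:
        files["truth"] = path / "truth.json"
        files["truth"].write_text(json.dumps(cohort.truth, indent=1))
    manifest = {
        "n_subjects": int(len(cohort.subjects)),
        "n_lipids": int(cohort.lipids.shape[1]),
        "seed": None if cohort.truth is None else cohort.truth.get("seed"),
        "spec_hash": None if cohort.truth is None else cohort.truth.get("spec_hash"),
    }
    files["manifest"] = path / "cohort_manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=1))
    return files


def read_cohort(path: str | Path) -> MatchedCohort:
    """Read a cohort written by :func:`write_cohort`; validates all invariants."""
    path = Path(path)
    subjects = pd.read_csv(path / "subjects.csv", float_precision="round_trip")
    lipids = pd.read_csv(
        path / "lipids.csv", index_col="subject_id", na_values=["", "NA"],
        keep_default_na=False, float_precision="round_trip",
    )
    truth = None
    sidecar = path / "truth.json"
    if sidecar.exists():
        truth = json.loads(sidecar.read_text())
    cohort = MatchedCohort(subjects=subjects, lipids=lipids, truth=truth)
    cohort.validate()
    return cohort
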