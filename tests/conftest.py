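import numpy as np
import pandas as pd
import pytest

from lipidnet.cohort import CohortSpec, generate_cohort
from lipidnet.preprocess import blom_transform, impute_half_min, strata_deviation


@pytest.fixture(scope="session")
def small_cohort():
    """150 strata, 20 lipids in 4 blocks, three planted effects."""
    spec = CohortSpec(
        n_strata=150,
        controls_per_case="draw",
        n_lipids=20,
        n_clusters=4,
        within_cluster_rho=0.5,
        true_effects={0: 0.5, 1: 0.3, 5: -0.4},
        missing_rate=0.05,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_blom(small_cohort):
    return blom_transform(impute_half_min(small_cohort.lipids))


@pytest.fixture(scope="session")
def small_deviations(small_cohort, small_blom):
    return strata_deviation(small_blom, small_cohort.strata)


@pytest.fixture
def paired_binary():
    """1:1 matched pairs with a binary exposure: 6 case-exposed-only pairs,
    3 control-exposed-only pairs, 4 concordant pairs."""

    def build(n_case_exposed=6, n_control_exposed=3, n_concordant=4):
        x, y, s = [], [], []
        sid = 0
        for _ in range(n_case_exposed):
            x += [1.0, 0.0]; y += [1, 0]; s += [sid] * 2; sid += 1
        for _ in range(n_control_exposed):
            x += [0.0, 1.0]; y += [1, 0]; s += [sid] * 2; sid += 1
        for _ in range(n_concordant):
            x += [1.0, 1.0]; y += [1, 0]; s += [sid] * 2; sid += 1
        return np.array(x)[:, None], np.array(y), np.array(s)

    return build
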