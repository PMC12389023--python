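import numpy as np
import pandas as pd
import pytest

from gmspipe import SimParams, annotate_cohort, simulate_cohort

COVARIATES = ["age", "sex", "site", "smoking", "diet_score"]


def make_cohort(seed=7, n=700, n_species=80, planted=None, **kwargs):
    """Simulated cohort with tight baselines so most species pass filtering."""
    lfc = np.zeros(n_species)
    if planted:
        for idx, value in planted.items():
            lfc[idx] = value
    params = SimParams(
        n_participants=n,
        n_species=n_species,
        baseline_log_sd=1.0,
        planted_lfc_noncarrier=lfc,
        seed=seed,
        **kwargs,
    )
    cohort, counts, truth = simulate_cohort(params)
    return annotate_cohort(cohort), counts, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Mid-sized cohort with no planted effects."""
    return make_cohort(seed=11)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with balanced +/-0.5 effects on the first 10 species."""
    planted = {i: 0.5 for i in range(5)}
    planted.update({i: -0.5 for i in range(5, 10)})
    return make_cohort(seed=13, n=900, planted=planted)


@pytest.fixture()
def tiny_counts():
    """Hand-built 4-species x 5-sample count table."""
    return pd.DataFrame(
        {
            "s1": [100, 300, 10, 2000],
            "s2": [200, 0, 10, 1500],
            "s3": [0, 0, 10, 900],
            "s4": [0, 0, 10, 1200],
            "s5": [0, 0, 10, 800],
        },
        index=["spA", "spB", "spC", "spD"],
    )
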