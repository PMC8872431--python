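import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import misutil as mu

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    return mu.SyntheticConfig(n_facilities=50, total_visits_target=6000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, volumes = mu.generate_cohort(small_config)
    return cohort


@pytest.fixture(scope="session")
def cohort50k():
    """Well-specified 50k-visit cohort with no planted outliers."""
    cfg = mu.SyntheticConfig(n_facilities=400, total_visits_target=50000, seed=101)
    cohort, volumes = mu.generate_cohort(cfg)
    return cohort, cfg


@pytest.fixture(scope="session")
def fits50k(cohort50k):
    """All three covariate-set fits on the collapsed 50k cohort."""
    cohort, cfg = cohort50k
    collapsed, _ = mu.collapse_categories(cohort)
    y = collapsed["outcome_used"].to_numpy()
    fits = {cs: mu.fit_logistic(mu.build_design(collapsed, cs), y)
            for cs in ("a", "b", "c")}
    return collapsed, cfg, fits, y


@pytest.fixture(scope="session")
def fitted50k(fits50k):
    """Covariate-set (a) fit on the collapsed 50k cohort."""
    collapsed, cfg, fits, y = fits50k
    return collapsed, cfg, fits["a"], y


def hand_cohort(patterns_and_outcomes, resources=mu.RESOURCES):
    """Build a minimal cohort from (bitstring, outcome) pairs."""
    rows = []
    for i, (pattern, y) in enumerate(patterns_and_outcomes):
        row = {"visit_id": f"V{i}", "patient_id": f"P{i}", "facility_id": "F0",
               "outcome_used": y}
        for r, b in zip(resources, pattern):
            row[r] = int(b)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def make_hand_cohort():
    return hand_cohort
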