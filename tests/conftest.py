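import numpy as np
import pandas as pd
import pytest

from tmiscreen import anthro
from tmiscreen.synthetic_cohort import SimCohortConfig, default_reference, generate_cohort


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def small_cohort(reference):
    """A ~1,200-child default-parameter cohort with derived columns,
    eligibility applied and endpoints attached."""
    cfg = SimCohortConfig(n_boys=650, n_girls=550, seed=20)
    raw = generate_cohort(cfg, reference).drop(columns=["age"])
    cohort = anthro.add_derived_columns(raw, reference)
    kept, _ = anthro.eligibility_filter(cohort)
    endpoints = anthro.endpoint_outcomes(kept)
    return kept, endpoints


@pytest.fixture(scope="session")
def default_cohort_10k(reference):
    """The calibrated default generator at 10,000 children (53.9% boys),
    shared by the heavier structural checks."""
    cfg = SimCohortConfig(n_boys=5394, n_girls=4606, seed=101)
    raw = generate_cohort(cfg, reference).drop(columns=["age"])
    cohort = anthro.add_derived_columns(raw, reference)
    kept, _ = anthro.eligibility_filter(cohort)
    endpoints = anthro.endpoint_outcomes(kept)
    return kept, endpoints


def make_planted_cohort(
    ow_threshold: float = 13.0,
    ob_threshold: float = 14.0,
    n_per_sex: int = 1000,
    ages=range(7, 19),
    lo: float = 10.0,
    hi: float = 18.0,
):
    """Separable cohort: each child's TMI is constant over age on a 0.1 grid
    spanning [lo, hi], and the endpoint outcomes are exactly the TMI
    thresholds applied to that constant value."""
    rows = []
    ep_rows = []
    for sex in ("M", "F"):
        values = np.round(np.linspace(lo, hi, n_per_sex), 1)
        for i, v in enumerate(values):
            cid = f"{sex}{i:05d}"
            ep_rows.append(
                {
                    "child_id": cid,
                    "sex": sex,
                    "endpoint_age": 17.0,
                    "endpoint_bmi_z": np.nan,
                    "status": "planted",
                    "ow_incl_ob": v >= ow_threshold,
                    "ob": v >= ob_threshold,
                }
            )
            for a in ages:
                rows.append(
                    {
                        "child_id": cid,
                        "sex": sex,
                        "age": a + 0.5,
                        "age_int": a,
                        "tmi": v,
                        "bmi": v * 1.5,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(ep_rows)
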