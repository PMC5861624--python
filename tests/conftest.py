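import numpy as np
import pandas as pd
import pytest

from csfpanel import (
    compute_ratios,
    design_from_config,
    generate_cohorts,
    load_config,
)
from csfpanel.cohort import FILE_COLUMNS


@pytest.fixture(scope="session")
def pipeline_config():
    return load_config()


@pytest.fixture(scope="session")
def default_cohorts(pipeline_config):
    """Test + validation cohorts generated from the packaged default design."""
    d_test = design_from_config(pipeline_config.test, seed=1234)
    d_val = design_from_config(pipeline_config.validation, seed=1235)
    return generate_cohorts(d_test, d_val)


@pytest.fixture(scope="session")
def test_cohort(default_cohorts):
    return default_cohorts[0]


@pytest.fixture(scope="session")
def validation_cohort(default_cohorts):
    return default_cohorts[1]


def make_cohort(rows):
    """Small hand-built cohort table; rows are dicts of column -> value."""
    base = {c: np.nan for c in FILE_COLUMNS}
    records = []
    for i, row in enumerate(rows):
        r = dict(base)
        r.update({"subject_id": f"s{i}", "cohort": "test", "confirmed": 0,
                  "sex": "female", "age_at_lp": 65.0})
        r.update(row)
        records.append(r)
    df = pd.DataFrame.from_records(records, columns=list(FILE_COLUMNS))
    return compute_ratios(df)


@pytest.fixture
def toy_cohort():
    """Six-group toy cohort with one fully observed biomarker."""
    rng = np.random.default_rng(99)
    rows = []
    for g, n, mu in [("AD", 12, 6.0), ("DLB", 8, 5.5), ("bvFTD", 8, 5.0),
                     ("PNFA", 6, 5.2), ("SD", 6, 5.1), ("HC", 8, 4.5)]:
        for _ in range(n):
            rows.append({
                "group": g,
                "abeta_1_42": float(np.exp(mu + 0.3 * rng.standard_normal())),
                "t_tau": float(np.exp(5.0 + 0.3 * rng.standard_normal())),
                "age_at_lp": float(rng.normal(64, 7)),
                "sex": "male" if rng.random() < 0.5 else "female",
                "onset_to_lp_months": (float(rng.lognormal(3.5, 0.4))
                                       if g != "HC" else np.nan),
            })
    return make_cohort(rows)
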