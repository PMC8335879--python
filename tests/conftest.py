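import numpy as np
import pandas as pd
import pytest

from survmice.core_data import Schema, TrialDataset, VariableSpec, dataset_from_pattern_counts
from survmice.synthetic_data import myeloma_schema


@pytest.fixture(scope="session")
def schema() -> Schema:
    return myeloma_schema()


# Published missing-data pattern counts of a 1852-subject training cohort
# (complete cases 1268) and an 849-subject test cohort (complete cases 361),
# used as printed inputs for the pattern/eligibility arithmetic.
TRAINING_PATTERNS = {
    (): 1268,
    ("ldh",): 187,
    ("ldh", "crp"): 107,
    ("crp",): 74,
    ("iss",): 46,
    ("iss", "ldh", "crp"): 30,
    ("iss", "ldh"): 28,
    ("who_ps",): 27,
    ("who_ps", "ldh"): 20,
    ("who_ps", "ldh", "crp"): 16,
    ("who_ps", "iss", "ldh", "crp"): 13,
    ("iss", "crp"): 9,
    ("who_ps", "iss", "ldh"): 9,
    ("who_ps", "crp"): 7,
    ("lw_ratio", "who_ps", "iss", "ldh", "crp"): 5,
    ("who_ps", "iss"): 4,
    ("lw_ratio",): 1,
    ("lw_ratio", "ldh", "crp"): 1,
}

TEST_PATTERNS = {
    (): 361,
    ("ldh",): 157,
    ("ldh", "crp"): 140,
    ("crp",): 91,
    ("iss", "ldh"): 42,
    ("iss", "ldh", "crp"): 33,
    ("iss",): 10,
    ("iss", "crp"): 7,
    ("lw_ratio", "ldh"): 2,
    ("who_ps", "ldh", "crp"): 2,
    ("lw_ratio", "crp"): 1,
    ("lw_ratio", "iss"): 1,
    ("who_ps", "iss", "ldh", "crp"): 1,
    ("who_ps", "crp"): 1,
}


@pytest.fixture(scope="session")
def training_pattern_dataset(schema) -> TrialDataset:
    return dataset_from_pattern_counts(schema, TRAINING_PATTERNS)


@pytest.fixture(scope="session")
def test_pattern_dataset(schema) -> TrialDataset:
    return dataset_from_pattern_counts(schema, TEST_PATTERNS)


@pytest.fixture(scope="session")
def simple_schema() -> Schema:
    """Minimal schema: time, event, two continuous + one 3-level ordinal."""
    return Schema([
        VariableSpec("time", role="outcome_time"),
        VariableSpec("event", role="outcome_event"),
        VariableSpec("x1", standardize=True),
        VariableSpec("x2", standardize=True),
        VariableSpec("grade", kind="ordinal", levels=("I", "II", "III")),
    ])


@pytest.fixture
def toy_cox_data():
    """Six subjects, all events, one binary covariate.

    The covariate alternates along the time order so the partial
    likelihood has an interior maximum (a monotone pattern would separate
    and send the estimate to infinity)."""
    return (
        pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]}),
        np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        np.ones(6, int),
    )


def simulate_survival(n, beta, rng, censor_rate=0.0, baseline=0.05):
    """Exponential PH data with linear predictor X @ beta."""
    p = len(beta)
    X = rng.normal(size=(n, p))
    pi = X @ np.asarray(beta)
    t_event = rng.exponential(1.0, n) / (baseline * np.exp(pi))
    if censor_rate > 0:
        c = rng.exponential(1.0 / censor_rate, n)
    else:
        c = np.full(n, np.inf)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    cols = [f"x{j + 1}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), time, event
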