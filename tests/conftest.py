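import warnings

import numpy as np
import pandas as pd
import pytest

import plasmasig as ps


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Pipeline components warn on benign fold-level events (empty screens,
    small strata); keep test output readable."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def null_cohort():
    """Default 202-patient cohort with no planted effects."""
    return ps.generate_cohort(ps.SimConfig(seed=7))


@pytest.fixture(scope="session")
def survival_signal_cohort():
    """Cohort with six planted prognostic proteins."""
    cfg = ps.survival_signature_config(seed=11)
    return ps.generate_cohort(cfg), cfg


def random_survival_data(rng, n, censor_frac=0.3):
    """Small random survival instance for oracle comparisons."""
    time = rng.exponential(2.0, n).round(2)  # rounding induces ties
    event = (rng.random(n) > censor_frac).astype(int)
    return time, event


def make_matrix(values, proteins=None, patients=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    patients = patients or [f"S{i}" for i in range(values.shape[1])]
    return ps.AbundanceMatrix(pd.DataFrame(values, index=proteins, columns=patients))
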