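import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from scorebias import (
    AppliedModelParams,
    HazardModelParams,
    VitDModelParams,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def canonical_vitd():
    return VitDModelParams()


@pytest.fixture(scope="session")
def canonical_hazard():
    return HazardModelParams()


@pytest.fixture(scope="session")
def applied_params():
    return AppliedModelParams()


@pytest.fixture(scope="session")
def cohort_5000(canonical_vitd, canonical_hazard):
    """One canonical survival cohort, shared across read-only tests."""
    return simulate_cohort(canonical_vitd, canonical_hazard, 5000, seed=42)


@pytest.fixture
def toy_survival():
    """Hand-built tie-free survival data, one binary covariate, n=8."""
    return pd.DataFrame(
        {
            "g": [1, 1, 1, 1, 0, 0, 0, 0],
            "time": [0.5, 1.1, 1.7, 2.3, 0.9, 1.9, 2.9, 3.5],
            "event": [1, 1, 1, 0, 1, 1, 1, 1],
        }
    )


def breslow_loglik_reference(beta, X, time, event):
    """Plain-loop Breslow log partial likelihood, independent of the package.

    Used as the oracle objective for small-sample checks of the Newton
    fitter: slow, literal, and obviously correct.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    ll = 0.0
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        lp_i = float(X[i] @ beta)
        denom = sum(np.exp(float(X[j] @ beta)) for j in risk)
        ll += lp_i - np.log(denom)
    return ll
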