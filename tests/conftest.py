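import numpy as np
import pandas as pd
import pytest

from deepcox import (SurvivalDataset, SimulationSpec, simulate_survival,
                     default_linear_beta)


def make_dataset(X, times, events, names=None, ids=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = names or [f"f{j + 1}" for j in range(X.shape[1])]
    ids = ids or [f"p{i + 1}" for i in range(X.shape[0])]
    return SurvivalDataset(
        features=pd.DataFrame(X, columns=names, index=ids),
        times=np.asarray(times, dtype=float),
        events=np.asarray(events, dtype=float))


@pytest.fixture
def toy_dataset():
    return make_dataset([[1.0, 0.0], [2.0, 1.0], [3.0, 0.0], [4.0, 1.0]],
                        times=[5.0, 3.0, 8.0, 1.0], events=[1, 0, 1, 1])


@pytest.fixture(scope="session")
def linear_cohort():
    """n=2000, p=10, ~30% censoring, moderate sign-alternating effects."""
    spec = SimulationSpec(n=2000, p=10, censoring_target=0.3, seed=1)
    ds, true_risk = simulate_survival(spec)
    return ds, true_risk, default_linear_beta(10)


def random_survival_instance(rng, n, tie_frac=0.3, censor_frac=0.5):
    """Random risk/times/events with tied times and mixed censoring."""
    risk = rng.normal(size=n)
    times = rng.integers(1, max(2, int(n * (1 - tie_frac))), size=n).astype(float)
    events = (rng.uniform(size=n) > censor_frac).astype(float)
    if not events.any():
        events[rng.integers(n)] = 1.0
    return risk, times, events
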