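import numpy as np
import pandas as pd
import pytest

from flexcess.lifetables import LifeTable
from flexcess.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def flat_lifetable():
    """Constant rates: 0.01 (cvd) and 0.03 (other) at every age/year."""

    ages = np.arange(0, 100)
    rows = []
    for cause, r in (("cvd", 0.01), ("other", 0.03)):
        for year in range(1960, 2011):
            rows.append(pd.DataFrame({"age": ages, "sex": "female",
                                      "year": year, "cause": cause, "rate": r}))
    return LifeTable(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 5000-subject cohort with its matching life table."""

    return simulate_cohort(SimulationConfig(n=5000, seed=99))


@pytest.fixture(scope="session")
def single_stratum_long():
    """All-cause long data for one stratum (c = 0 everywhere)."""

    rng = np.random.default_rng(314)
    n = 600
    t_lat = rng.weibull(1.2, n) * 4.0
    cens = rng.uniform(1.0, 12.0, n)
    time = np.minimum(t_lat, cens)
    event = (t_lat <= cens).astype(int)
    return pd.DataFrame({
        "id": np.arange(n), "stratum": "all", "c": 0, "d": event,
        "time": time, "entry": 0.0, "expected_rate": 0.0,
        "z": rng.binomial(1, 0.5, n).astype(float),
    })
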