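import numpy as np
import pandas as pd
import pytest

from micox.data import SurvivalData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cox_data(seed=0, n=50, p=5, beta_scale=0.5, censor_scale=2.0):
    """Random proportional-hazards data for solver/oracle cross-checks."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, p))
    beta = r.normal(size=p) * beta_scale
    t_event = r.exponential(scale=np.exp(-X @ beta))
    t_cens = r.exponential(scale=censor_scale, size=n)
    time = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    sv = SurvivalData.from_arrays(time, status)
    return X, sv, beta


@pytest.fixture
def cox_data():
    return make_cox_data()


@pytest.fixture
def small_expression(rng):
    ids = [f"P{i}" for i in range(6)]
    genes = ["g1", "g2", "g3"]
    return pd.DataFrame(rng.normal(size=(6, 3)), index=ids, columns=genes)
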