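import numpy as np
import pytest

import respkit as rk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, t=50, tr_s=0.8, scale=0.1):
    """A generic random motion trace for oracle comparisons."""
    params = rng.normal(0.0, scale, size=(t, 6))
    return rk.MotionTrace(params=params, tr_s=tr_s)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-subject, 2-run cohort with BOLD, shared across tests."""
    return rk.gen_cohort(10, seed=202, n_runs=2)


@pytest.fixture(scope="session")
def toy_timeseries():
    """Deterministic 12x4 parcel timeseries with two 2-parcel networks."""
    rng = np.random.default_rng(7)
    data = rng.normal(size=(12, 4))
    ids = ["a", "b", "c", "d"]
    nets = {"a": "n1", "b": "n1", "c": "n2", "d": "n2"}
    return rk.ParcelTimeseries(data=data, parcel_ids=ids, network_of=nets, tr_s=0.8)
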