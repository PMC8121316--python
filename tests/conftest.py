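import numpy as np
import pytest
from hypothesis import settings

import guvpore as g

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def chol_membrane():
    return g.get_membrane("DOPG/DOPC/chol(46/39/15)")


@pytest.fixture
def dopg_dopc_membrane():
    return g.get_membrane("DOPG/DOPC(40/60)")


@pytest.fixture
def chol_kinetics():
    return g.CHOL_KINETICS


@pytest.fixture
def dopg_dopc_kinetics():
    return g.DOPG_DOPC_KINETICS


def make_records(times, window=60.0, sigma_c=5e-3, group="grp"):
    """Build rupture records from a list of times; None means censored."""
    records = []
    for i, t in enumerate(times):
        if t is None or t > window:
            records.append(
                g.RuptureRecord(f"g{i:04d}", group, sigma_c, censored=True, window=window)
            )
        else:
            records.append(
                g.RuptureRecord(f"g{i:04d}", group, sigma_c, time=float(t), window=window)
            )
    return records


def simulate_exponential_records(k, n, rng, window=60.0, sigma_c=5e-3):
    """Uncensored-exponential draws truncated by the observation window."""
    return make_records(rng.exponential(1.0 / k, size=n), window=window, sigma_c=sigma_c)
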