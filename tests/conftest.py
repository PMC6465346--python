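import numpy as np
import pytest

from msytools import coverage as cov


@pytest.fixture
def one_male_one_female():
    return [
        cov.SampleProfile("m1", "male", 20.0),
        cov.SampleProfile("f1", "female", 20.0, 0.2),
    ]


@pytest.fixture
def small_coverage_sim():
    from msytools import simulate as sim

    params = sim.SimCoverageParams(
        n_males=4, n_females=2, n_windows_per_class=200, seed=11
    )
    return sim.simulate_coverage(params)


def rng(seed=0):
    return np.random.default_rng(seed)
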