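import numpy as np
import pytest

import weibull_perturb as wp


@pytest.fixture(scope="session")
def case1():
    return wp.case1_fixture()


@pytest.fixture(scope="session")
def case2():
    return wp.case2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_censored_sample(rng, M=50, alpha=3.0, beta=1.5, p=0.8):
    """A valid time-censored Weibull sample drawn from the study design.

    Retries degenerate draws (possible at heavy censoring with small M)
    with fresh seeds so callers always receive a usable sample.
    """
    for _ in range(100):
        config = wp.SimulationConfig(
            M=M, alpha_true=alpha, beta_true=beta, p=p,
            seed=int(rng.integers(2**31)),
        )
        try:
            return wp.generate_sample(config)
        except wp.DegenerateSampleError:
            continue
    raise AssertionError("could not draw a valid sample in 100 attempts")
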