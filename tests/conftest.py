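import numpy as np
import pytest

from growthmodes import (
    ModelParams,
    sample_trajectory,
    simulate_lineage,
)
from growthmodes.params import GrowthMode, NoiseKind


@pytest.fixture(scope="session")
def exp_params():
    """Data-like exponential adder: <Td>=212 min, CV_lambda=sigma_n=0.15."""
    return ModelParams()


@pytest.fixture(scope="session")
def lin_params():
    """Data-like linear adder: size-additive timing noise of 0.15 <Lb>."""
    return ModelParams(
        growth_mode=GrowthMode.LINEAR,
        noise_kind=NoiseKind.SIZE_ADDITIVE,
        sigma_bd=0.15,
    )


@pytest.fixture(scope="session")
def exp_lineage(exp_params):
    return simulate_lineage(exp_params, 2500)


@pytest.fixture(scope="session")
def exp_trajectories(exp_params, exp_lineage):
    rng = np.random.default_rng(17)
    return [
        sample_trajectory(c, exp_params, dt=4.0, post_division_window=12.0, rng=rng)
        for c in exp_lineage[:800]
        if c.Td > 4.0
    ]
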