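import numpy as np
import pytest

from chronomap.design import build_exp1_design, build_exp2_design
from chronomap.simulate import make_truth_chronomap


@pytest.fixture(scope="session")
def exp1_runs():
    """Two experiment-1 runs (events, scan)."""
    return build_exp1_design(2, seed=11)


@pytest.fixture(scope="session")
def exp2_run():
    """One ascending experiment-2 run at full length (10 cycles)."""
    return build_exp2_design("ascending", 10, seed=7)


@pytest.fixture(scope="session")
def exp2_run_pair():
    asc = build_exp2_design("ascending", 10, seed=7)
    desc = build_exp2_design("descending", 10, seed=8)
    return asc, desc


@pytest.fixture()
def small_truth():
    return make_truth_chronomap(shape=(8, 8, 1), duration_range=(0.2, 1.0),
                                sigma_star=0.2, seed=3, voxel_size=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
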