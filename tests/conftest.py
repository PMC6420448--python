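import numpy as np
import pytest

from contextwm.design import (
    DesignParams,
    build_design,
    exp1_design_params,
    exp3_design_params,
    generate_learning_schedule,
)


@pytest.fixture(scope="session")
def exp1_design():
    return build_design(exp1_design_params(), seed=11)


@pytest.fixture(scope="session")
def exp3_design():
    return build_design(exp3_design_params(), seed=7)


@pytest.fixture(scope="session")
def exp3_schedule(exp3_design):
    return generate_learning_schedule(exp3_design, seed=13)


@pytest.fixture(scope="session")
def minimal_design():
    return build_design(DesignParams(n_sets=1, words_per_set=4, words_per_trial=4), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
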