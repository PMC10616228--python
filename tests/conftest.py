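import numpy as np
import pytest

from pkst.assessment import ItemParams
from pkst.fixtures import (
    fig2_goal_space,
    fig2_skill_map,
    ktol_structure,
    table4_params,
    tol_goal_space,
)
from pkst.spaces import build_tol_space


@pytest.fixture(scope="session")
def tol_space():
    return build_tol_space()


@pytest.fixture(scope="session")
def tol_gs():
    """Full-space shortest-path goal space, one-move problems dropped."""
    return tol_goal_space(drop_one_move=True)


@pytest.fixture(scope="session")
def fig2_gs():
    return fig2_goal_space()


@pytest.fixture(scope="session")
def fig2_sm():
    return fig2_skill_map()


@pytest.fixture(scope="session")
def ktol():
    return ktol_structure()


@pytest.fixture(scope="session")
def table4():
    return table4_params()


@pytest.fixture()
def example1_item_params():
    """The per-problem careless-error and lucky-guess rates of the worked CMP example."""
    return ItemParams(
        beta={"s1": 0.004, "s3": 0.03, "s4": 0.02, "s7": 0.01, "s8": 0.007},
        eta={"s1": 1e-6, "s3": 5e-5, "s4": 4e-5, "s7": 0.007, "s8": 0.08},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
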