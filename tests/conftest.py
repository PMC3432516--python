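import numpy as np
import pandas as pd
import pytest

from gshflux.expression import ExpressionMatrix
from gshflux.model import build_default_gsh_model
from gshflux.steadystate import SteadyStateSolver


@pytest.fixture(scope="session")
def gsh_model():
    return build_default_gsh_model()


@pytest.fixture(scope="session")
def gsh_solver(gsh_model):
    return SteadyStateSolver(gsh_model)


@pytest.fixture(scope="session")
def gsh_reference_state(gsh_solver):
    state = gsh_solver.solve()
    assert state.converged
    return state


@pytest.fixture
def toy_expression():
    """Hand-built table: case replicates {8, 12}, control replicates {10, 10}."""
    df = pd.DataFrame(
        {
            "CTRL_1": [10.0, 100.0],
            "CTRL_2": [10.0, 100.0],
            "CASE_1": [8.0, 100.0],
            "CASE_2": [12.0, 100.0],
        },
        index=["GENEA", "GENEB"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
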