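import numpy as np
import pytest

from mauthner.params import CellState, CircuitState, ModelParameters


@pytest.fixture(scope="session")
def default_params():
    return ModelParameters()


@pytest.fixture(scope="session")
def dominant_params():
    return ModelParameters.for_phenotype("dominant")


@pytest.fixture(scope="session")
def subordinate_params():
    return ModelParameters.for_phenotype("subordinate")


@pytest.fixture(scope="session")
def dominant_qss(dominant_params):
    from mauthner.simulate import quasi_steady_state

    return quasi_steady_state(dominant_params)


@pytest.fixture(scope="session")
def subordinate_qss(subordinate_params):
    from mauthner.simulate import quasi_steady_state

    return quasi_steady_state(subordinate_params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_circuit_state(rng) -> CircuitState:
    """A physically plausible random state for kernel-vs-reference checks."""
    def cell():
        return CellState(
            v=float(rng.uniform(-80, 40)),
            n=float(rng.uniform(0, 1)),
            Ca=float(rng.uniform(0, 6)),
            s=float(rng.uniform(0, 1)),
            E_net=float(rng.uniform(0.5, 1.2)),
        )

    return CircuitState(cell1=cell(), cell2=cell())
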