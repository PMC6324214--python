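"""Shared fixtures: packaged circuits/parameters and the (expensive)
400-point bifurcation diagrams, computed once per session."""

import pytest

from emtcircuits import default_snail_grid, load_circuit, load_params
from emtcircuits.bifurcation import sweep_bifurcation


@pytest.fixture(scope="session")
def simplified_circuit():
    return load_circuit("simplified")


@pytest.fixture(scope="session")
def simplified_params():
    return load_params("simplified_default")


@pytest.fixture(scope="session")
def extended_circuit():
    return load_circuit("extended")


@pytest.fixture(scope="session")
def extended_params():
    return load_params("extended_default")


@pytest.fixture(scope="session")
def cd44_circuit():
    return load_circuit("cd44")


@pytest.fixture(scope="session")
def snail_grid_400():
    return default_snail_grid(400)


@pytest.fixture(scope="session")
def simplified_diagram(simplified_circuit, simplified_params, snail_grid_400):
    return sweep_bifurcation(simplified_circuit, simplified_params,
                             snail_grid_400, seed=3)


@pytest.fixture(scope="session")
def extended_diagram(extended_circuit, extended_params, snail_grid_400):
    return sweep_bifurcation(extended_circuit, extended_params,
                             snail_grid_400, seed=3)
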