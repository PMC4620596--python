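import pytest

from cfba import (
    binary_light,
    build_synechocystis_model,
    build_toy_model,
    make_grid,
)


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def syn_model():
    return build_synechocystis_model()


@pytest.fixture()
def small_toy_scenario():
    """Toy model scenario on a coarse grid (fast solves)."""
    grid = make_grid(24, 8, 24)
    return grid, binary_light(grid)
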