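import numpy as np
import pytest

from leverxlink import build_hex_grid, place_levers, preset


@pytest.fixture(scope="session")
def grid_1um():
    return build_hex_grid(1000.0, 2.5)


@pytest.fixture(scope="session")
def field_d100(grid_1um):
    return place_levers(grid_1um, 100.0, seed=11)


@pytest.fixture(scope="session")
def spec_441():
    return preset("441")


@pytest.fixture(scope="session")
def spec_841():
    return preset("841")


def min_pairwise_distance(points: np.ndarray) -> float:
    from scipy.spatial.distance import pdist

    return float(pdist(points).min())
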