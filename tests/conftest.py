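import numpy as np
import pytest

from spamv.datatypes import SpatialMultiOmics
from spamv.synthetic_data import FactorLayout, SimParams, simulate


@pytest.fixture(scope="session")
def small_layout() -> FactorLayout:
    """12x12 grid with one private zone per modality and one shared zone."""
    zones = [(0, 0, 0, 4, 4), (1, 8, 8, 4, 4), (2, 4, 4, 4, 4)]
    kinds = {-1: "background", 0: "private_1", 1: "private_2", 2: "shared"}
    return FactorLayout(12, 12, zones, kinds)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(n_features_1=60, n_features_2=30, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_layout, small_params):
    return simulate(small_layout, small_params)


@pytest.fixture(scope="session")
def default_sim():
    from spamv.synthetic_data import default_layout

    return simulate(default_layout(), SimParams(seed=11))


@pytest.fixture()
def toy_data() -> SpatialMultiOmics:
    """Tiny dense two-modality container for shape-level tests."""
    rng = np.random.default_rng(3)
    n = 16
    coords = np.array([[i // 4, i % 4] for i in range(n)], dtype=float)
    return SpatialMultiOmics(
        matrices=[rng.poisson(5.0, (n, 12)).astype(float),
                  rng.poisson(5.0, (n, 8)).astype(float)],
        coords=coords,
        feature_names=[[f"a{j}" for j in range(12)], [f"b{j}" for j in range(8)]],
        spot_ids=[f"s{i}" for i in range(n)],
        modality_kinds=["transcriptome", "metabolome"],
    )
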