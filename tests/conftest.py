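import numpy as np
import pytest

from taluscam import synthetic as S
from taluscam import trees as T


@pytest.fixture
def cherry():
    """Two-tip tree with unit branches."""
    return T.parse_tree("(a:1.0,b:1.0);")


@pytest.fixture
def star8():
    """Eight-tip star tree, equal branches of length 2."""
    tips = ",".join(f"s{i}:2.0" for i in range(8))
    return T.parse_tree(f"({tips});")


@pytest.fixture
def yule32():
    return S.simulate_tree(32, seed=7)


@pytest.fixture
def noiseless_talus():
    spec = S.SyntheticTalusSpec(
        trochlea_radius=3.0, shelf_offset=1.5, mesh_resolution=0.1, seed=0
    )
    return S.make_synthetic_talus(spec)


def cylinder_sector_points(
    radius: float = 3.0,
    arc_deg: float = 120.0,
    n: int = 200,
    axis: str = "x",
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Points on a partial cylinder about a coordinate axis."""
    rng = np.random.default_rng(seed)
    arc = np.deg2rad(arc_deg)
    u = rng.uniform(-2.0, 2.0, n)
    phi = rng.uniform(-arc / 2, arc / 2, n)
    P = np.column_stack(
        [u, radius * np.cos(phi), radius * np.sin(phi)]
    )
    if axis == "z":
        P = P[:, [1, 2, 0]]
    if noise_sd > 0:
        P = P + rng.normal(0, noise_sd, P.shape)
    return P
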