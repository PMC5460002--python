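import numpy as np
import pandas as pd
import pytest

from hydrorefugia.catchment import SpringCatchment
from hydrorefugia.landscape import Landscape, WaterLayer


@pytest.fixture
def catchment() -> SpringCatchment:
    """A mid-range sloping catchment (Hi ~ 3.3, GRT ~ 44 y)."""
    return SpringCatchment(B=2000.0, alpha=0.05, A=4e6, k0=300.0, n_e=0.1,
                           spring_id="mid")


@pytest.fixture
def flat_catchment() -> SpringCatchment:
    """A flat catchment: alpha = 0, GRT = 100 y."""
    return SpringCatchment(B=3000.0, alpha=0.0, A=9e6, k0=30.0, n_e=0.1,
                           spring_id="flat")


def random_catchments(n: int, seed: int, hi_max: float = 5.0):
    """Randomized small catchments with slope number capped (so a plain
    central-difference oracle grid resolves the advection)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        B = 10 ** rng.uniform(2.5, 4.2)
        k0 = 10 ** rng.uniform(0.5, 3.5)
        n_e = 10 ** rng.uniform(-2, -0.6)
        eta0 = 30.0
        # slope chosen so Hi = Bx tan(a)/eta0 stays below hi_max
        hi = rng.uniform(0.0, hi_max)
        alpha = np.arctan(hi * eta0 / B) * 0.99
        A = 2.0 * B ** 2 * 10 ** rng.normal(0, 0.2)
        out.append(SpringCatchment(B=B, alpha=float(alpha), A=A, k0=k0,
                                   n_e=n_e, spring_id=f"r{i}"))
    return out


@pytest.fixture
def flat_corridor():
    """Flat 5 x 200 landscape with a 1-cell natal patch at column 2 and a
    target spring far to the east."""
    shape = (5, 200)
    elev = np.zeros(shape)
    land = Landscape(elevation=elev, roughness=np.zeros(shape),
                     slope=np.zeros(shape), cost=np.ones(shape))
    patch = np.zeros(shape, dtype=int)
    patch[2, 2] = 1
    patch[2, 180] = 2
    reg = pd.DataFrame({"patch_id": [1, 2],
                        "feature_class": ["perennial_spring",
                                          "perennial_spring"]})
    return land, WaterLayer(patch_id=patch, registry=reg)


def make_flat_landscape(shape=(40, 40)):
    z = np.zeros(shape)
    return Landscape(elevation=z, roughness=np.zeros(shape),
                     slope=np.zeros(shape), cost=np.ones(shape))


def make_two_patch_water(shape=(40, 40), a=(20, 5), b=(20, 34)):
    patch = np.zeros(shape, dtype=int)
    patch[a] = 1
    patch[b] = 2
    reg = pd.DataFrame({"patch_id": [1, 2],
                        "feature_class": ["perennial_spring", "fresh_lake"]})
    return WaterLayer(patch_id=patch, registry=reg)
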