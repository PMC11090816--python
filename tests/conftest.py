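import numpy as np
import pytest

from phytoclim.fitting import classify_env_zones
from phytoclim.soil import simulate_soil_moisture
from phytoclim.synthetic import generate_climatology
from phytoclim.ttr import uptake_ceiling


@pytest.fixture(scope="session")
def world():
    """A 20x20 synthetic world with soil moisture and land forcing arrays."""
    clim = generate_climatology(20, 20, seed=7)
    moisture = simulate_soil_moisture(clim).moisture
    mask = clim.grid.land_mask
    t = np.stack([clim.tmean[m][mask] for m in range(12)], axis=1)
    w = np.stack([moisture[m][mask] for m in range(12)], axis=1)
    r = np.stack([clim.rad[m][mask] for m in range(12)], axis=1)
    return {
        "clim": clim,
        "moisture": moisture,
        "t": t,
        "w": w,
        "rad": r,
        "a_max": {p: uptake_ceiling(t, r, clim.co2, p) for p in ("C3", "C4")},
    }


@pytest.fixture(scope="session")
def env_zones(world):
    return classify_env_zones(world["clim"], world["moisture"], k=10, seed=3)
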