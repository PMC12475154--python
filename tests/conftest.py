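import numpy as np
import pytest

from paleoniche import (
    Continent,
    GridSpec,
    NicheParams,
    WorldConfig,
    generate_niche_pool,
    make_world,
    shelf_mask,
)


@pytest.fixture
def grid12() -> GridSpec:
    return GridSpec.regular(12, 12)


@pytest.fixture
def island_world(grid12):
    """One small continent in a gradient climate on a 12x12 grid."""
    cfg = WorldConfig(
        equator_sst=30.0,
        pole_sst=-2.0,
        seasonal_amplitude=6.0,
        continents=(Continent(-20, 20, 90, 180),),
    )
    return make_world(cfg, grid12, 50.0)


@pytest.fixture
def island_mask(island_world):
    return shelf_mask(island_world)


@pytest.fixture
def small_pool():
    return generate_niche_pool(NicheParams(n_niches=10, seed=7))


def random_toy_instance(rng, n_lat=None, n_lon=None, n_niches=None):
    """A random world/mask/pool triple on a tiny grid for oracle checks."""
    n_lat = n_lat or int(rng.integers(6, 13))
    n_lon = n_lon or int(rng.integers(6, 13))
    n_niches = n_niches or int(rng.integers(1, 11))
    grid = GridSpec.regular(n_lat, n_lon)
    # random continent, possibly crossing the longitude seam
    lat0 = float(rng.uniform(-70, 30))
    lon0 = float(rng.uniform(0, 360))
    cont = Continent(lat0, lat0 + float(rng.uniform(15, 60)),
                     lon0, lon0 + float(rng.uniform(30, 150)))
    cfg = WorldConfig(
        equator_sst=float(rng.uniform(18, 34)),
        pole_sst=float(rng.uniform(-2, 6)),
        seasonal_amplitude=float(rng.uniform(0, 10)),
        noise_sd=float(rng.uniform(0, 2)),
        continents=(cont,),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    world = make_world(cfg, grid, float(rng.uniform(0, 500)))
    mask = shelf_mask(world)
    pool = generate_niche_pool(
        NicheParams(n_niches=n_niches, seed=int(rng.integers(0, 2**31 - 1)))
    )
    return world, mask, pool
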