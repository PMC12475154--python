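import numpy as np
import pytest

from paleoniche import (
    Continent,
    GridSpec,
    NicheParams,
    WorldConfig,
    annual_occupancy,
    count_patches,
    generate_niche_pool,
    global_richness,
    make_world,
    months_suitable,
    richness_map,
    shelf_mask,
)
from paleoniche.niche import NichePool

from conftest import random_toy_instance
from oracles import flood_fill_patches, monthly_mean_richness_loop, months_suitable_loop


def _fixed_pool(intervals):
    lower = np.array([a for a, _ in intervals], float)
    upper = np.array([b for _, b in intervals], float)
    params = NicheParams(n_niches=len(intervals))
    return NichePool(params=params, lower=lower, upper=upper)


@pytest.mark.parametrize("seed", range(8))
def test_months_suitable_matches_triple_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    world, mask, pool = random_toy_instance(rng)
    got = months_suitable(pool, world, mask)
    want = months_suitable_loop(pool, world, mask)
    np.testing.assert_array_equal(got, want)


def test_months_suitable_independent_of_block_size():
    rng = np.random.default_rng(99)
    world, mask, pool = random_toy_instance(rng, n_niches=10)
    a = months_suitable(pool, world, mask, block=1)
    b = months_suitable(pool, world, mask, block=3)
    c = months_suitable(pool, world, mask, block=1024)
    np.testing.assert_array_equal(a, b)
    np.testing.assert_array_equal(a, c)


def test_all_temperature_niche_suits_every_month(island_world, island_mask):
    pool = _fixed_pool([(-2.0, 44.0)])
    ms = months_suitable(pool, island_world, island_mask)
    assert np.all(ms == 12)


def test_disjoint_niche_suits_nowhere(grid12):
    w = make_world(WorldConfig(equator_sst=20, pole_sst=20, seasonal_amplitude=0,
                               continents=(Continent(-10, 10, 90, 150),)), grid12, 0.0)
    mask = shelf_mask(w)
    pool = _fixed_pool([(24.0, 44.0)])
    assert np.all(months_suitable(pool, w, mask) == 0)


@pytest.mark.parametrize("seed", range(8))
def test_monthly_mean_richness_matches_loop_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    world, mask, pool = random_toy_instance(rng)
    rm = richness_map(pool, world, mask, mode="monthly_mean")
    want = monthly_mean_richness_loop(pool, world, mask)
    np.testing.assert_allclose(rm.richness[mask.cells], want, atol=1e-12)
    assert np.all(rm.richness[~mask.cells] == 0)


def test_single_broad_niche_gives_unit_richness(island_world, island_mask):
    pool = _fixed_pool([(-2.0, 44.0)])
    for mode in ("monthly_mean", "annual"):
        rm = richness_map(pool, island_world, island_mask, mode=mode)
        np.testing.assert_allclose(rm.richness[island_mask.cells], 1.0)


def test_epsilon_threshold_boundary(island_world, island_mask):
    pool = _fixed_pool([(0.0, 30.0)])
    ms = months_suitable(pool, island_world, island_mask)
    cube8 = annual_occupancy(pool, island_world, island_mask, epsilon=8)
    np.testing.assert_array_equal(cube8.occupied, ms >= 8)
    with pytest.raises(ValueError):
        annual_occupancy(pool, island_world, island_mask, epsilon=0)
    with pytest.raises(ValueError):
        annual_occupancy(pool, island_world, island_mask, epsilon=13)


def test_occupancy_monotone_in_epsilon(island_world, island_mask, small_pool):
    """Raising epsilon shrinks every niche's occupancy, so the occupied
    cube and the without-speciation count are non-increasing.  (The
    with-speciation patch total is NOT monotone: a shrinking patch can
    split in two, so it is deliberately not asserted here.)"""
    prev_counts = None
    prev_occ = None
    for eps in range(1, 13):
        cube = annual_occupancy(small_pool, island_world, island_mask, epsilon=eps)
        counts = global_richness(small_pool, island_world, island_mask, epsilon=eps)
        if prev_counts is not None:
            assert counts.global_without_speciation <= prev_counts.global_without_speciation
            assert np.all(cube.occupied <= prev_occ)
        prev_counts, prev_occ = counts, cube.occupied


def test_count_patches_basics():
    assert count_patches(np.zeros((5, 8), bool)) == 0
    blob = np.zeros((5, 8), bool)
    blob[1:3, 2:5] = True
    assert count_patches(blob) == 1
    blob[4, 6] = True
    assert count_patches(blob) == 2


def test_count_patches_wraps_longitude_seam():
    occ = np.zeros((4, 10), bool)
    occ[1, 0] = occ[1, -1] = True  # one patch across the seam
    assert count_patches(occ) == 1
    # diagonal wrap only under 8-connectivity
    occ2 = np.zeros((4, 10), bool)
    occ2[1, 0] = occ2[2, -1] = True
    assert count_patches(occ2, connectivity=2) == 1
    assert count_patches(occ2, connectivity=1) == 2


@pytest.mark.parametrize("seed", range(10))
def test_count_patches_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    occ = rng.random((20, 20)) < 0.35
    for conn in (1, 2):
        assert count_patches(occ, connectivity=conn) == flood_fill_patches(occ, conn)


def test_speciation_never_below_no_speciation():
    rng = np.random.default_rng(4)
    for _ in range(10):
        world, mask, pool = random_toy_instance(rng)
        sc = global_richness(pool, world, mask)
        assert sc.global_with_speciation >= sc.global_without_speciation
        empty = sc.per_niche_patches == 0
        # a niche with no patches contributes to neither count
        assert sc.global_without_speciation == int((~empty).sum())


def test_two_symmetric_continents_double_dual_shelf_counts():
    grid = GridSpec.regular(24, 24)
    cfg = WorldConfig(
        equator_sst=26, pole_sst=2, seasonal_amplitude=0,
        continents=(Continent(-55, -45, 90, 180), Continent(45, 55, 90, 180)),
    )
    w = make_world(cfg, grid, 0.0)
    mask = shelf_mask(w)
    pool = generate_niche_pool(NicheParams(n_niches=200, seed=3))
    sc = global_richness(pool, w, mask)
    cube = annual_occupancy(pool, w, mask)
    lat_idx = np.where(mask.cells)[0]
    south = lat_idx < grid.n_lat // 2
    for k in range(len(pool)):
        occ = cube.occupied[k]
        on_south = occ[south].any()
        on_north = occ[~south].any()
        if on_south and on_north:
            # shelves are disjoint and climate symmetric: the patch count
            # doubles the single-shelf count
            full = np.zeros(grid.shape, bool)
            full[lat_idx[occ], np.where(mask.cells)[1][occ]] = True
            south_half = full.copy()
            south_half[grid.n_lat // 2 :, :] = False
            assert sc.per_niche_patches[k] == flood_fill_patches(full)
            assert sc.per_niche_patches[k] == 2 * flood_fill_patches(south_half)


def test_fragmentation_does_not_decrease_speciation_count():
    grid = GridSpec.regular(18, 24)
    climate = dict(equator_sst=26, pole_sst=0, seasonal_amplitude=0)
    whole = make_world(
        WorldConfig(continents=(Continent(-10, 10, 60, 180),), **climate), grid, 0.0
    )
    split = make_world(
        WorldConfig(
            continents=(Continent(-10, 10, 60, 105), Continent(-10, 10, 135, 180)),
            **climate,
        ),
        grid,
        0.0,
    )
    pool = generate_niche_pool(NicheParams(n_niches=300, seed=12))
    sc_whole = global_richness(pool, whole, shelf_mask(whole))
    sc_split = global_richness(pool, split, shelf_mask(split))
    assert sc_split.global_with_speciation >= sc_whole.global_with_speciation


def test_richness_invariant_under_niche_reordering(island_world, island_mask):
    pool = generate_niche_pool(NicheParams(n_niches=30, seed=8))
    perm = np.random.default_rng(0).permutation(30)
    shuffled = NichePool(params=pool.params, lower=pool.lower[perm], upper=pool.upper[perm])
    a = richness_map(pool, island_world, island_mask)
    b = richness_map(shuffled, island_world, island_mask)
    np.testing.assert_allclose(a.richness, b.richness)


def test_richness_equivariant_under_longitude_rotation():
    grid = GridSpec.regular(12, 12)
    pool = generate_niche_pool(NicheParams(n_niches=50, seed=6))
    shift = 4
    dlon = 360.0 / grid.n_lon * shift
    w0 = make_world(WorldConfig(continents=(Continent(-20, 20, 60, 150),)), grid, 0.0)
    w1 = make_world(WorldConfig(continents=(Continent(-20, 20, 60 + dlon, 150 + dlon),)),
                    grid, 0.0)
    r0 = richness_map(pool, w0, shelf_mask(w0))
    r1 = richness_map(pool, w1, shelf_mask(w1))
    np.testing.assert_allclose(np.roll(r0.richness, shift, axis=1), r1.richness)
    s0 = global_richness(pool, w0, shelf_mask(w0))
    s1 = global_richness(pool, w1, shelf_mask(w1))
    assert s0.global_with_speciation == s1.global_with_speciation
    assert s0.global_without_speciation == s1.global_without_speciation


def test_empty_mask_gives_zero_counts(grid12):
    w = make_world(WorldConfig(), grid12, 0.0)
    with pytest.warns(UserWarning):
        mask = shelf_mask(w)
    pool = generate_niche_pool(NicheParams(n_niches=10, seed=1))
    sc = global_richness(pool, w, mask)
    assert sc.global_with_speciation == 0 and sc.global_without_speciation == 0
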