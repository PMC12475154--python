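"""Niche projection: monthly suitability, richness maps, the
epsilon-month annual-persistence rule, and allopatric speciation by
patch counting.

A niche occupies a shelf cell in a given month when the monthly SST lies
inside its interval; it maintains annually in the cell when at least
``epsilon`` of the 12 months are suitable (default 8).  Without
speciation each niche with any annual occupancy contributes one species;
with speciation each isolated patch (connected component with longitude
wrap) of its annual occupancy map counts as a separate species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as _sk_label

from .grid import GridSpec
from .niche import NichePool
from .shelf import ShelfMask
from .world import WorldSlice

DEFAULT_EPSILON = 8


def _check_grids(pool: NichePool, world: WorldSlice, mask: ShelfMask) -> None:
    if mask.grid.shape != world.grid.shape:
        raise ValueError("mask and world are on different grids")


def _masked_sst(world: WorldSlice, mask: ShelfMask) -> np.ndarray:
    """(n_masked_cells, 12) SST samples; NaN months are never suitable."""
    return world.sst[mask.cells, :]


def months_suitable(
    pool: NichePool, world: WorldSlice, mask: ShelfMask, block: int = 1024
) -> np.ndarray:
    """Count of suitable months, shape (n_niches, n_masked_cells).

    Computed in niche blocks to bound memory; the result is independent
    of the block size.
    """
    _check_grids(pool, world, mask)
    sst = _masked_sst(world, mask)  # (c, 12)
    n = len(pool)
    out = np.empty((n, sst.shape[0]), dtype=np.int16)
    for start in range(0, n, block):
        lo = pool.lower[start : start + block, None, None]
        hi = pool.upper[start : start + block, None, None]
        ok = (sst[None, :, :] >= lo) & (sst[None, :, :] <= hi)
        out[start : start + block] = ok.sum(axis=2)
    return out


@dataclass(frozen=True)
class RichnessMap:
    grid: GridSpec
    richness: np.ndarray
    mode: str  # "monthly_mean" or "annual"
    mask_cells: np.ndarray


def _monthly_counts(pool: NichePool, sst: np.ndarray) -> np.ndarray:
    """Species count per (cell, month) via sorted interval stabbing.

    The number of intervals covering temperature t equals
    #{lower <= t} - #{upper < t}; exact integer arithmetic, no per-niche
    loop.  NaN samples get count 0.
    """
    lo = np.sort(pool.lower)
    hi = np.sort(pool.upper)
    t = sst.ravel()
    finite = np.isfinite(t)
    counts = np.zeros(t.shape, dtype=np.int64)
    tf = t[finite]
    counts[finite] = np.searchsorted(lo, tf, side="right") - np.searchsorted(
        hi, tf, side="left"
    )
    return counts.reshape(sst.shape)


def richness_map(
    pool: NichePool,
    world: WorldSlice,
    mask: ShelfMask,
    mode: str = "monthly_mean",
    epsilon: int = DEFAULT_EPSILON,
) -> RichnessMap:
    """Per-cell species richness on the shelf mask.

    mode="monthly_mean": mean over the 12 months of the per-month count
    of suitable niches (the mapping convention).  mode="annual": count of
    niches whose suitable-month total reaches epsilon.
    """
    _check_grids(pool, world, mask)
    sst = _masked_sst(world, mask)
    grid_map = np.zeros(world.grid.shape, dtype=float)
    if mode == "monthly_mean":
        vals = _monthly_counts(pool, sst).mean(axis=1)
    elif mode == "annual":
        ms = months_suitable(pool, world, mask)
        vals = (ms >= int(epsilon)).sum(axis=0).astype(float)
    else:
        raise ValueError("mode must be 'monthly_mean' or 'annual'")
    grid_map[mask.cells] = vals
    return RichnessMap(grid=world.grid, richness=grid_map, mode=mode, mask_cells=mask.cells)


@dataclass(frozen=True)
class OccupancyCube:
    """Per-niche boolean annual occupancy on the masked cells."""

    epsilon: int
    mask_cells: np.ndarray
    months_count: np.ndarray   # (n_niches, n_masked_cells)
    occupied: np.ndarray       # boolean, same shape


def annual_occupancy(
    pool: NichePool, world: WorldSlice, mask: ShelfMask, epsilon: int = DEFAULT_EPSILON
) -> OccupancyCube:
    if not 1 <= int(epsilon) <= 12:
        raise ValueError("epsilon must be between 1 and 12")
    ms = months_suitable(pool, world, mask)
    return OccupancyCube(
        epsilon=int(epsilon), mask_cells=mask.cells, months_count=ms, occupied=ms >= int(epsilon)
    )


def count_patches(occupancy_map: np.ndarray, connectivity: int = 2) -> int:
    """Connected components of a boolean map with longitude wrap.

    connectivity=2 is 8-neighbour (default), 1 is 4-neighbour.  No wrap
    across the poles.  Components touching both sides of the longitude
    seam are merged with a union-find pass.
    """
    occ = np.asarray(occupancy_map, dtype=bool)
    if not occ.any():
        return 0
    labels = _sk_label(occ, connectivity=connectivity)
    n = labels.max()
    if occ.shape[1] < 2:
        return int(n)
    parent = list(range(n + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    left = labels[:, 0]
    right = labels[:, -1]
    n_lat = occ.shape[0]
    offsets = (0,) if connectivity == 1 else (-1, 0, 1)
    for i in range(n_lat):
        if right[i] == 0:
            continue
        for di in offsets:
            j = i + di
            if 0 <= j < n_lat and left[j] != 0:
                union(right[i], left[j])
    roots = {find(l) for l in range(1, n + 1)}
    return len(roots)


@dataclass(frozen=True)
class SpeciesCounts:
    per_niche_patches: np.ndarray
    global_with_speciation: int
    global_without_speciation: int


def global_richness(
    pool: NichePool,
    world: WorldSlice,
    mask: ShelfMask,
    epsilon: int = DEFAULT_EPSILON,
    connectivity: int = 2,
) -> SpeciesCounts:
    """Global species counts with and without allopatric speciation.

    Without speciation: niches with non-empty annual occupancy.  With
    speciation: total isolated patches over all niches.
    """
    cube = annual_occupancy(pool, world, mask, epsilon)
    occ = cube.occupied
    nonempty = occ.any(axis=1)
    patches = np.zeros(len(pool), dtype=np.int64)
    if nonempty.any():
        full = np.zeros(world.grid.shape, dtype=bool)
        idx = np.where(mask.cells)
        for k in np.nonzero(nonempty)[0]:
            full[:] = False
            full[idx[0], idx[1]] = occ[k]
            patches[k] = count_patches(full, connectivity=connectivity)
    return SpeciesCounts(
        per_niche_patches=patches,
        global_with_speciation=int(patches.sum()),
        global_without_speciation=int(nonempty.sum()),
    )
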