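"""Shelf masks: the marine cells "around continents" where biodiversity
is evaluated.

Eight variants are admissible: rings of one or two cells around land,
optionally intersected with a bathymetry threshold (<600, <1000 or
<1500 m below sea level).  Adjacency is Chebyshev (8-neighbour) with
longitude wrap by default; Manhattan (4-neighbour) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .grid import GridSpec, cell_areas
from .world import WorldSlice, chebyshev_distance_to_land

DEPTH_LIMITS = (None, 600.0, 1000.0, 1500.0)
RING_WIDTHS = (1, 2)


@dataclass(frozen=True)
class ShelfVariant:
    """One of the eight admissible shelf characterisations."""

    ring_width: int = 2
    depth_limit: float | None = None

    def __post_init__(self) -> None:
        if self.ring_width not in RING_WIDTHS:
            raise ValueError("ring_width must be 1 or 2")
        if self.depth_limit not in DEPTH_LIMITS:
            raise ValueError(f"depth_limit must be one of {DEPTH_LIMITS}")

    def label(self) -> str:
        d = "none" if self.depth_limit is None else f"{int(self.depth_limit)}m"
        return f"ring{self.ring_width}_{d}"


def all_variants() -> list[ShelfVariant]:
    """Enumerate the eight admissible ring-width x depth-limit variants."""
    return [ShelfVariant(w, d) for w, d in product(RING_WIDTHS, DEPTH_LIMITS)]


@dataclass(frozen=True)
class ShelfMask:
    grid: GridSpec
    cells: np.ndarray
    variant: ShelfVariant

    def __post_init__(self) -> None:
        if self.cells.shape != self.grid.shape:
            raise ValueError("mask shape mismatch")

    @property
    def n_cells(self) -> int:
        return int(self.cells.sum())


def _manhattan_distance_to_land(land: np.ndarray, max_dist: int) -> np.ndarray:
    dist = np.full(land.shape, max_dist + 1, dtype=int)
    reach = land.copy()
    dist[reach] = 0
    for d in range(1, max_dist + 1):
        grown = reach | np.roll(reach, 1, axis=1) | np.roll(reach, -1, axis=1)
        grown[1:, :] |= reach[:-1, :]
        grown[:-1, :] |= reach[1:, :]
        newly = grown & ~reach
        dist[newly] = d
        reach = grown
        if reach.all():
            break
    return dist


def shelf_mask(
    world: WorldSlice, variant: ShelfVariant = ShelfVariant(), adjacency: str = "chebyshev"
) -> ShelfMask:
    """Marine cells within ring_width cells of land, optionally shallower
    than the depth limit (strict <)."""
    land = world.landmask
    if not (~land).any():
        raise ValueError("no marine cells")
    if not land.any():
        warnings.warn("no land cells: shelf mask is empty", stacklevel=2)
        return ShelfMask(world.grid, np.zeros(world.grid.shape, dtype=bool), variant)
    if adjacency == "chebyshev":
        dist = chebyshev_distance_to_land(land, variant.ring_width)
    elif adjacency == "manhattan":
        dist = _manhattan_distance_to_land(land, variant.ring_width)
    else:
        raise ValueError("adjacency must be 'chebyshev' or 'manhattan'")
    cells = (~land) & (dist <= variant.ring_width)
    if variant.depth_limit is not None:
        with np.errstate(invalid="ignore"):
            cells &= world.bathymetry < variant.depth_limit
    return ShelfMask(world.grid, cells, variant)


def shelf_area(mask: ShelfMask, areas: np.ndarray | None = None) -> float:
    """Total area (km^2) of the masked cells on the WGS-84 ellipsoid."""
    if areas is None:
        areas = cell_areas(mask.grid)
    if areas.shape != mask.cells.shape:
        raise ValueError("area grid shape mismatch")
    return float(areas[mask.cells].sum())
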