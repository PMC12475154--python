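"""Driver indices per time slice.

LBG: latitudinal biodiversity gradient, the mean richness per latitude
row over masked cells.  LCI: latitudinal continental index, the count of
shelf cells holding at least one species (summed over latitudes).
LBG-weighted LCI weights each latitude's occupied-cell count by the mean
richness there.  Temperature-density diagnostics histogram the monthly
SST samples on the shelf.  Age series (e.g. the external continental
fragmentation index) are resampled with shape-preserving monotone cubic
(PCHIP) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grid import GridSpec
from .occupancy import DEFAULT_EPSILON, RichnessMap, annual_occupancy
from .niche import NichePool
from .shelf import ShelfMask
from .world import WorldSlice


@dataclass(frozen=True)
class LatProfile:
    lat_centers: np.ndarray
    value: np.ndarray  # NaN where a latitude row has no masked cells

    def __post_init__(self) -> None:
        if self.lat_centers.shape != self.value.shape:
            raise ValueError("profile axes mismatch")


@dataclass(frozen=True)
class AgeSeries:
    """Values indexed by age in Ma, strictly decreasing toward present."""

    ages: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be matching 1-D arrays")
        d = np.diff(ages)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ages must be strictly monotone")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")


def lbg(map_: RichnessMap) -> LatProfile:
    """Mean richness per latitude row over the masked cells of that row."""
    n_lat = map_.grid.n_lat
    vals = np.full(n_lat, np.nan)
    for i in range(n_lat):
        row_mask = map_.mask_cells[i]
        if row_mask.any():
            vals[i] = map_.richness[i, row_mask].mean()
    return LatProfile(lat_centers=map_.grid.lat_centers, value=vals)


def occupied_cells_per_latitude(
    pool: NichePool,
    world: WorldSlice,
    mask: ShelfMask,
    epsilon: int = DEFAULT_EPSILON,
    months: str = "annual",
) -> np.ndarray:
    """Per-latitude count of masked cells with >=1 species.

    months="annual" (default) uses the epsilon-qualified annual presence;
    months="sum" instead sums, over the 12 months, the per-month count of
    cells with at least one suitable niche.
    """
    cube = annual_occupancy(pool, world, mask, epsilon)
    counts = np.zeros(world.grid.n_lat, dtype=float)
    lat_idx = np.where(mask.cells)[0]
    if months == "annual":
        present = cube.occupied.any(axis=0)  # per masked cell
        for i, p in zip(lat_idx, present):
            counts[i] += bool(p)
    elif months == "sum":
        sst = world.sst[mask.cells, :]  # (c, 12)
        lo = pool.lower[:, None, None]
        hi = pool.upper[:, None, None]
        # per (cell, month): any suitable niche
        any_niche = ((sst[None] >= lo) & (sst[None] <= hi)).any(axis=0)
        per_cell = any_niche.sum(axis=1).astype(float)  # cell-months
        for i, c in zip(lat_idx, per_cell):
            counts[i] += c
    else:
        raise ValueError("months must be 'annual' or 'sum'")
    return counts


def lci(
    pool: NichePool,
    world: WorldSlice,
    mask: ShelfMask,
    epsilon: int = DEFAULT_EPSILON,
    months: str = "annual",
) -> float:
    """Latitudinal continental index: occupied shelf cells summed over
    latitudes."""
    return float(occupied_cells_per_latitude(pool, world, mask, epsilon, months).sum())


def lbg_weighted_lci(
    pool: NichePool,
    world: WorldSlice,
    mask: ShelfMask,
    lbg_profile: LatProfile,
    epsilon: int = DEFAULT_EPSILON,
    months: str = "annual",
) -> float:
    """Sum over latitudes of occupied-cell count times the LBG value."""
    if lbg_profile.lat_centers.shape != world.grid.lat_centers.shape or not np.allclose(
        lbg_profile.lat_centers, world.grid.lat_centers
    ):
        raise ValueError("LBG profile is on a different latitude axis")
    counts = occupied_cells_per_latitude(pool, world, mask, epsilon, months)
    w = np.where(np.isnan(lbg_profile.value), 0.0, lbg_profile.value)
    return float((counts * w).sum())


@dataclass(frozen=True)
class TemperatureDensity:
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_bin_center: float
    mean_sst: float


def temperature_density(
    world: WorldSlice, mask: ShelfMask, bin_edges: np.ndarray | None = None
) -> TemperatureDensity:
    """Histogram of (cell, month) SST samples on the mask.

    Default bins span -2 to 41 deg C at 1 deg C.  Also reports the modal
    bin centre and the mean SST of the samples.
    """
    if bin_edges is None:
        bin_edges = np.arange(-2.0, 42.0, 1.0)
    samples = world.sst[mask.cells, :].ravel()
    samples = samples[np.isfinite(samples)]
    counts, edges = np.histogram(samples, bins=bin_edges)
    if samples.size == 0:
        return TemperatureDensity(edges, counts, np.nan, np.nan)
    k = int(np.argmax(counts))
    return TemperatureDensity(
        bin_edges=edges,
        counts=counts,
        modal_bin_center=float(0.5 * (edges[k] + edges[k + 1])),
        mean_sst=float(samples.mean()),
    )


def interpolate_to_ages(series: AgeSeries, target_ages) -> AgeSeries:
    """Shape-preserving (monotone Hermite / PCHIP) interpolation onto
    target ages.  No extrapolation: targets must lie inside the source
    age span."""
    target = np.asarray(target_ages, dtype=float)
    a, v = series.ages, series.values
    order = np.argsort(a)
    a_sorted, v_sorted = a[order], v[order]
    if target.min() < a_sorted[0] - 1e-12 or target.max() > a_sorted[-1] + 1e-12:
        raise ValueError("target ages outside the source age span (no extrapolation)")
    interp = PchipInterpolator(a_sorted, v_sorted)
    return AgeSeries(ages=target, values=interp(np.clip(target, a_sorted[0], a_sorted[-1])),
                     label=series.label)
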