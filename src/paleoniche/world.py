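"""Synthetic palaeo-world generator.

Builds gridded time slices (monthly sea-surface temperature, landmask,
bathymetry) with the statistical structure the biodiversity analysis
assumes: a pole-to-equator thermal gradient, a hemispherically anti-phased
seasonal cycle, configurable continental blocks, and a distance-to-coast
shelf bathymetry.  Multi-slice drift scenarios move and fragment
continents across geological ages.

The generator stands in for gridded climate-model output; real fields in
the same netCDF dialect are read through :mod:`paleoniche.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GridSpec

SEA_FREEZE_C = -2.0  # sea water freezing point; SST floor


@dataclass(frozen=True)
class Continent:
    """A rectangular landmass in degrees; lon_min > lon_max wraps the seam."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def contains(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        in_lat = (lat >= self.lat_min) & (lat <= self.lat_max)
        if self.lon_max - self.lon_min >= 360.0:
            return in_lat
        lo = self.lon_min % 360.0
        hi = self.lon_max % 360.0
        lonm = lon % 360.0
        if lo <= hi:
            in_lon = (lonm >= lo) & (lonm <= hi)
        else:  # wraps the 0/360 seam
            in_lon = (lonm >= lo) | (lonm <= hi)
        return in_lat & in_lon

    @property
    def centroid_lat(self) -> float:
        return 0.5 * (self.lat_min + self.lat_max)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of one synthetic time slice.

    equator_sst / pole_sst : annual-mean SST (deg C) at the equator and
        at the poles; the meridional profile is pole + (eq - pole) cos^2(lat).
    seasonal_amplitude : peak seasonal half-range (deg C) reached at the
        poles; anti-phased between hemispheres, zero at the equator,
        Northern-Hemisphere maximum in July.
    continents : rectangular landmasses.
    shelf_slope : metres of depth gained per cell of distance from land.
    abyssal_depth : depth cap (m) for the open ocean.
    noise_sd : iid Gaussian noise added to every (cell, month) sample.
    seed : base seed; each slice derives its own stream from (seed, age).
    """

    equator_sst: float = 28.0
    pole_sst: float = -2.0
    seasonal_amplitude: float = 8.0
    continents: tuple[Continent, ...] = ()
    shelf_slope: float = 300.0
    abyssal_depth: float = 4000.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class WorldSlice:
    """One geological time slice on a regular lat-lon grid.

    sst has shape (n_lat, n_lon, 12) in deg C, NaN on land; landmask is
    True on emerged land; bathymetry is metres below sea level on marine
    cells and NaN on land.
    """

    grid: GridSpec
    age: float
    landmask: np.ndarray
    bathymetry: np.ndarray
    sst: np.ndarray

    def __post_init__(self) -> None:
        if self.sst.shape != self.grid.shape + (12,):
            raise ValueError("sst must have shape (n_lat, n_lon, 12)")
        if self.landmask.shape != self.grid.shape:
            raise ValueError("landmask shape mismatch")
        if self.bathymetry.shape != self.grid.shape:
            raise ValueError("bathymetry shape mismatch")
        marine = ~self.landmask
        if np.isnan(self.sst[marine]).any():
            raise ValueError("sst must be defined on all marine cells")
        if np.nanmin(self.sst[marine], initial=np.inf) < SEA_FREEZE_C - 1e-9:
            raise ValueError("sst below sea-water freezing point")
        if np.nanmin(self.bathymetry[marine], initial=np.inf) < 0:
            raise ValueError("bathymetry must be >= 0 on marine cells")

    @property
    def marine(self) -> np.ndarray:
        return ~self.landmask


def _slice_rng(seed: int, age: float) -> np.random.Generator:
    # one independent stream per slice, order-insensitive
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(round(age * 1000))]))


def land_from_continents(grid: GridSpec, continents) -> np.ndarray:
    lat2d = grid.lat_centers[:, None] * np.ones((1, grid.n_lon))
    lon2d = np.ones((grid.n_lat, 1)) * grid.lon_centers[None, :]
    land = np.zeros(grid.shape, dtype=bool)
    for c in continents:
        land |= c.contains(lat2d, lon2d)
    return land


def chebyshev_distance_to_land(land: np.ndarray, max_dist: int) -> np.ndarray:
    """Chebyshev distance (in cells) from each cell to the nearest land cell.

    Longitude (axis 1) wraps; latitude does not.  Distances beyond
    ``max_dist`` are reported as ``max_dist + 1``.  All-ocean grids get
    ``max_dist + 1`` everywhere.
    """
    dist = np.full(land.shape, max_dist + 1, dtype=int)
    reach = land.copy()
    dist[reach] = 0
    for d in range(1, max_dist + 1):
        grown = reach.copy()
        # dilate one step: lon shifts wrap, lat shifts clip
        grown |= np.roll(reach, 1, axis=1) | np.roll(reach, -1, axis=1)
        up = np.zeros_like(reach)
        up[1:, :] = grown[:-1, :] | reach[:-1, :]
        down = np.zeros_like(reach)
        down[:-1, :] = grown[1:, :] | reach[1:, :]
        grown |= up | down
        newly = grown & ~reach
        dist[newly] = d
        reach = grown
        if reach.all():
            break
    return dist


def make_world(config: WorldConfig, grid: GridSpec, age: float) -> WorldSlice:
    """Generate one synthetic time slice.

    Monthly SST at latitude phi, month m (0 = January):

        sst = pole + (eq - pole) cos^2(phi)
              + amplitude * sin(phi) * cos(2 pi (m - 6) / 12)
              + noise

    clipped below at -2 deg C.  Bathymetry is shelf_slope times the
    cell distance to the nearest land cell, capped at abyssal_depth.
    """
    land = land_from_continents(grid, config.continents)
    if land.all():
        raise ValueError("no marine cells: continents cover the whole grid")

    phi = np.deg2rad(grid.lat_centers)[:, None, None]
    months = np.arange(12)[None, None, :]
    annual = config.pole_sst + (config.equator_sst - config.pole_sst) * np.cos(phi) ** 2
    seasonal = config.seasonal_amplitude * np.sin(phi) * np.cos(2 * np.pi * (months - 6) / 12.0)
    sst = np.broadcast_to(annual + seasonal, grid.shape + (12,)).copy()
    if config.noise_sd > 0:
        rng = _slice_rng(config.seed, age)
        sst = sst + rng.normal(0.0, config.noise_sd, size=sst.shape)
    sst = np.maximum(sst, SEA_FREEZE_C)
    sst[land, :] = np.nan

    if land.any():
        max_d = int(np.ceil(config.abyssal_depth / max(config.shelf_slope, 1e-9)))
        max_d = min(max_d, max(grid.n_lat, grid.n_lon))
        dist = chebyshev_distance_to_land(land, max_d)
        depth = np.minimum(dist * config.shelf_slope, config.abyssal_depth)
    else:
        depth = np.full(grid.shape, config.abyssal_depth)
    depth = depth.astype(float)
    depth[land] = np.nan

    return WorldSlice(grid=grid, age=float(age), landmask=land, bathymetry=depth, sst=sst)


def _interp_continents(c0: tuple[Continent, ...], c1: tuple[Continent, ...], t: float):
    if len(c0) != len(c1):
        # topology change (fragmentation/assembly): switch at mid-segment
        return c0 if t < 0.5 else c1
    out = []
    for a, b in zip(c0, c1):
        out.append(
            Continent(
                lat_min=a.lat_min + t * (b.lat_min - a.lat_min),
                lat_max=a.lat_max + t * (b.lat_max - a.lat_max),
                lon_min=a.lon_min + t * (b.lon_min - a.lon_min),
                lon_max=a.lon_max + t * (b.lon_max - a.lon_max),
            )
        )
    return tuple(out)


def make_drift_scenario(configs, grid: GridSpec, ages) -> list[WorldSlice]:
    """One WorldSlice per age (ages strictly decreasing, old -> young).

    ``configs`` is either one WorldConfig per age, or a shorter sequence
    of waypoints spread evenly over the age axis; between waypoints the
    continent rectangles are interpolated linearly (a change in continent
    count switches configuration at mid-segment, supporting fragmentation
    waypoints).  Climate parameters interpolate linearly as well.
    """
    ages = [float(a) for a in ages]
    if any(nxt >= prv for prv, nxt in zip(ages, ages[1:])):
        raise ValueError("ages must be strictly decreasing (old to young)")
    configs = list(configs)
    n = len(ages)
    if len(configs) == n:
        per_age = configs
    elif 2 <= len(configs) < n:
        per_age = []
        for i in range(n):
            pos = i / (n - 1) * (len(configs) - 1)
            k = min(int(pos), len(configs) - 2)
            t = pos - k
            a, b = configs[k], configs[k + 1]
            per_age.append(
                replace(
                    a,
                    equator_sst=a.equator_sst + t * (b.equator_sst - a.equator_sst),
                    pole_sst=a.pole_sst + t * (b.pole_sst - a.pole_sst),
                    seasonal_amplitude=a.seasonal_amplitude
                    + t * (b.seasonal_amplitude - a.seasonal_amplitude),
                    continents=_interp_continents(a.continents, b.continents, t),
                )
            )
    else:
        raise ValueError("need one config per age or >=2 waypoint configs")
    return [make_world(c, grid, a) for c, a in zip(per_age, ages)]
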