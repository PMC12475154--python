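"""Grid geometry: regular lat-lon grids and WGS-84 cell areas.

All modules share the conventions fixed here: latitude centres ascending
(-90 -> 90), longitude periodic (column 0 adjacent to the last column),
cell-centre registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# WGS-84 ellipsoid
_WGS84_A = 6378.137          # equatorial radius, km
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)
_WGS84_E = np.sqrt(1.0 - (_WGS84_B / _WGS84_A) ** 2)  # first eccentricity


@dataclass(frozen=True)
class GridSpec:
    """A regular latitude-longitude grid, cell-centre registered.

    Parameters
    ----------
    lat_centers : array of latitude cell centres in degrees, strictly
        increasing, all within (-90, 90).
    lon_centers : array of longitude cell centres in degrees, uniformly
        spaced; the axis is periodic.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        if lat.ndim != 1 or lon.ndim != 1:
            raise ValueError("lat_centers and lon_centers must be 1-D")
        if np.any(np.diff(lat) <= 0):
            raise ValueError("lat_centers must be strictly increasing")
        if lat[0] <= -90 or lat[-1] >= 90:
            raise ValueError("lat_centers must lie strictly inside (-90, 90)")
        dlon = np.diff(lon)
        if lon.size > 1 and not np.allclose(dlon, dlon[0]):
            raise ValueError("longitude spacing must be uniform")

    @property
    def n_lat(self) -> int:
        return self.lat_centers.size

    @property
    def n_lon(self) -> int:
        return self.lon_centers.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def lat_edges(self) -> np.ndarray:
        """Cell-edge latitudes (n_lat + 1 values), clipped to +/-90."""
        lat = self.lat_centers
        inner = 0.5 * (lat[:-1] + lat[1:])
        if lat.size == 1:
            half = 1.0
        else:
            half = 0.5 * (lat[1] - lat[0])
        first = max(-90.0, lat[0] - half)
        half_last = 0.5 * (lat[-1] - lat[-2]) if lat.size > 1 else 1.0
        last = min(90.0, lat[-1] + half_last)
        return np.concatenate([[first], inner, [last]])

    @classmethod
    def regular(cls, n_lat: int, n_lon: int) -> "GridSpec":
        """Equally spaced global grid with cell centres off the poles."""
        dlat = 180.0 / n_lat
        lat = -90.0 + dlat * (np.arange(n_lat) + 0.5)
        dlon = 360.0 / n_lon
        lon = dlon * (np.arange(n_lon) + 0.5)
        return cls(lat, lon)


def _zone_area(lat_deg: np.ndarray) -> np.ndarray:
    """Ellipsoid surface area (km^2) between the equator and latitude.

    Closed form for the area of a spherical zone generalised to the
    WGS-84 ellipsoid; signed (negative south of the equator).
    """
    e = _WGS84_E
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    s = np.sin(phi)
    term = s / (1.0 - e**2 * s**2) + np.arctanh(e * s) / e
    return np.pi * _WGS84_A**2 * (1.0 - e**2) * term


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Area in km^2 of every cell, shape (n_lat, n_lon).

    Each latitude band's ellipsoid zone area is split equally among the
    n_lon columns (longitude spacing is uniform).
    """
    edges = grid.lat_edges()
    band = _zone_area(edges[1:]) - _zone_area(edges[:-1])
    per_cell = band / grid.n_lon
    return np.repeat(per_cell[:, None], grid.n_lon, axis=1)


def earth_surface_area() -> float:
    """Total WGS-84 surface area in km^2 (for validation)."""
    return float(_zone_area(np.array(90.0)) - _zone_area(np.array(-90.0)))
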