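"""netCDF and CSV input/output.

World slices are stored in a small netCDF dialect: dimensions ``lat``,
``lon``, ``month``; variables ``sst`` (deg C, NaN on land), ``landmask``
(0/1 or boolean) and ``bathymetry`` (metres below sea level, NaN on
land); a global attribute ``age_ma``.  The same dialect is the ingestion
format for real palaeoclimate fields regridded to lat-lon.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .grid import GridSpec
from .indices import AgeSeries
from .world import WorldSlice

_ENGINE = "scipy"  # NetCDF3 via scipy


def write_world(world: WorldSlice, path) -> None:
    ds = xr.Dataset(
        {
            "sst": (("lat", "lon", "month"), world.sst),
            "landmask": (("lat", "lon"), world.landmask.astype(np.int8)),
            "bathymetry": (("lat", "lon"), world.bathymetry),
        },
        coords={
            "lat": world.grid.lat_centers,
            "lon": world.grid.lon_centers,
            "month": np.arange(1, 13),
        },
        attrs={"age_ma": float(world.age)},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_world(path) -> WorldSlice:
    try:
        ds = xr.open_dataset(path, engine=_ENGINE)
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable world slice {path}: {exc}") from exc
    with ds:
        for var in ("sst", "landmask", "bathymetry"):
            if var not in ds:
                raise ValueError(f"{path}: missing variable '{var}'")
        if "month" not in ds.dims or ds.sizes["month"] != 12:
            raise ValueError(f"{path}: needs a 12-step 'month' dimension")
        if "age_ma" not in ds.attrs:
            raise ValueError(f"{path}: missing attribute 'age_ma'")
        grid = GridSpec(ds["lat"].values.astype(float), ds["lon"].values.astype(float))
        sst = ds["sst"].transpose("lat", "lon", "month").values.astype(float)
        land = ds["landmask"].values.astype(bool)
        bathy = ds["bathymetry"].values.astype(float)
        age = float(ds.attrs["age_ma"])
    return WorldSlice(grid=grid, age=age, landmask=land, bathymetry=bathy, sst=sst)


def read_world_dir(path) -> list[WorldSlice]:
    """All ``*.nc`` slices in a directory, sorted old to young."""
    files = sorted(Path(path).glob("*.nc"))
    if not files:
        raise ValueError(f"no .nc files in {path}")
    worlds = [read_world(f) for f in files]
    worlds.sort(key=lambda w: -w.age)
    return worlds


def age_series_to_csv(series: AgeSeries, path) -> None:
    pd.DataFrame({"age_ma": series.ages, "value": series.values}).to_csv(path, index=False)


def age_series_from_csv(path, label: str = "") -> AgeSeries:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    age_col = cols.get("age_ma") or cols.get("age") or df.columns[0]
    val_col = cols.get("value") or [c for c in df.columns if c != age_col][0]
    return AgeSeries(
        df[age_col].to_numpy(dtype=float),
        df[val_col].to_numpy(dtype=float),
        label=label or str(val_col),
    )
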