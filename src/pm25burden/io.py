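"""Readers and writers for the gridded and tabular interchange formats.

Gridded fields travel as CF-style NetCDF (dimensions ``lat``, ``lon``
and optionally ``week``; variables ``pm25`` or ``population``); tables
as headed CSV.  Every writer has a paired reader used downstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr

from .exposure import SECTORS, ScenarioSet
from .grids import GriddedField, GridSpec

_ENGINE = "scipy"  # NETCDF3_CLASSIC


def _dataset(field: GriddedField, name: str) -> xr.Dataset:
    spec = field.spec
    return xr.Dataset(
        {name: (("lat", "lon"), field.values)},
        coords={"lat": spec.lat_centers, "lon": spec.lon_centers},
        attrs={
            "lat_min": spec.lat_min,
            "lat_max": spec.lat_max,
            "lon_min": spec.lon_min,
            "lon_max": spec.lon_max,
        },
    )


def _spec_from(ds: xr.Dataset) -> GridSpec:
    return GridSpec(
        n_lat=ds.sizes["lat"],
        n_lon=ds.sizes["lon"],
        lat_min=float(ds.attrs["lat_min"]),
        lat_max=float(ds.attrs["lat_max"]),
        lon_min=float(ds.attrs["lon_min"]),
        lon_max=float(ds.attrs["lon_max"]),
    )


def write_field(field: GriddedField, path: str | Path, name: str = "pm25") -> None:
    _dataset(field, name).to_netcdf(path, engine=_ENGINE)


def read_field(path: str | Path, name: str = "pm25") -> GriddedField:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return GriddedField(ds[name].values.copy(), _spec_from(ds))


def write_weekly(
    annual: GriddedField, weekly: np.ndarray, path: str | Path, name: str = "pm25"
) -> None:
    """Annual field plus its weekly stack in one file (week dimension)."""
    ds = _dataset(annual, name)
    ds[f"{name}_weekly"] = (("week", "lat", "lon"), weekly)
    ds = ds.assign_coords(week=np.arange(weekly.shape[0]))
    ds.to_netcdf(path, engine=_ENGINE)


def read_weekly(
    path: str | Path, name: str = "pm25"
) -> tuple[GriddedField, np.ndarray]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        spec = _spec_from(ds)
        return (
            GriddedField(ds[name].values.copy(), spec),
            ds[f"{name}_weekly"].values.copy(),
        )


def write_scenarios(scen: ScenarioSet, path: str | Path) -> None:
    """Control and sector-off annual fields in one NetCDF file."""
    ds = _dataset(scen.control, "pm25_control")
    for sector in SECTORS:
        ds[f"pm25_off_{sector}"] = (("lat", "lon"), scen.sector_off[sector].values)
    ds.to_netcdf(path, engine=_ENGINE)


def read_scenarios(path: str | Path) -> ScenarioSet:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        spec = _spec_from(ds)
        control = GriddedField(ds["pm25_control"].values.copy(), spec)
        off = {
            sector: GriddedField(ds[f"pm25_off_{sector}"].values.copy(), spec)
            for sector in SECTORS
        }
    return ScenarioSet(control=control, sector_off=off)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
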