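"""NetCDF and delimited-text readers/writers.

All gridded interchange uses CF-flavoured NetCDF (classic format via the
scipy backend): coordinate variables ``lon``/``lat`` (and ``time`` in ka BP
where applicable), a ``units`` attribute on every data variable, NaN for
missing cells, and integer surface-type codes 0=ocean, 1=land, 2=land_ice
with a ``flag_meanings`` attribute. Longitudes are normalized to [-180, 180)
on read, reordering the data to keep the axis monotonic.

Forcing tables and proxy records travel as delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .emulator import COEF_NAMES, EmulatorModel, SnapshotSet, VariableModel
from .downscale import ReferenceClimatology
from .forcings import ForcingTable, NormalizationStats, FORCING_COLUMNS
from .grid import ClimateField, Grid
from .masks import LEVEL_NAMES, SurfaceTypeGrid

__all__ = [
    "read_climate_netcdf", "write_climate_netcdf",
    "read_mask", "write_mask", "read_forcings", "write_forcings",
    "read_snapshots", "write_snapshots", "read_reference", "write_reference",
    "read_emulator", "write_emulator",
]

_ENGINE = "scipy"

_TIME_ATTRS = {"units": "ka BP", "positive_direction": "into the past"}


def _normalize_lon(lon: np.ndarray, values: np.ndarray, lon_axis: int):
    """Map longitudes into [-180, 180) and reorder data to keep lon monotonic."""
    lon = ((np.asarray(lon, float) + 180.0) % 360.0) - 180.0
    order = np.argsort(lon)
    if not np.all(order == np.arange(lon.size)):
        values = np.take(values, order, axis=lon_axis)
        lon = lon[order]
    return lon, values


def write_climate_netcdf(field: ClimateField, path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {field.name: (("time", "lat", "lon"), field.values)},
        coords={"time": field.times, "lat": field.grid.lat, "lon": field.grid.lon},
    )
    ds[field.name].attrs["units"] = field.units
    for k, v in field.attrs.items():
        if isinstance(v, (str, int, float)):
            ds[field.name].attrs[k] = v
    ds["time"].attrs.update(_TIME_ATTRS)
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_climate_netcdf(path, variable: str | None = None) -> ClimateField:
    """Read a gridded variable; requires lon/lat coordinates and units."""
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds = ds.load()
    lon_name = next((n for n in ("lon", "longitude") if n in ds.coords), None)
    lat_name = next((n for n in ("lat", "latitude") if n in ds.coords), None)
    if lon_name is None or lat_name is None:
        raise ValueError(f"{path}: missing lon/lat coordinate variables")
    if variable is None:
        cands = [v for v in ds.data_vars if set(ds[v].dims) >= {lon_name, lat_name}]
        if not cands:
            raise ValueError(f"{path}: no gridded data variable found")
        variable = cands[0]
    da = ds[variable]
    if "units" not in da.attrs:
        raise ValueError(f"{path}: variable {variable!r} has no units attribute")
    dims = list(da.dims)
    vals = da.values.astype(float)
    if "time" in dims:
        da_t = ds["time"].values.astype(float)
        vals = np.moveaxis(vals, dims.index("time"), 0)
        dims.remove("time")
        dims.insert(0, "time")
    else:
        da_t = np.array([0.0])
        vals = vals[None]
    # now dims = (time, ?, ?): put lat before lon
    if dims.index(lat_name) > dims.index(lon_name):
        vals = np.swapaxes(vals, 1, 2)
    lon = ds[lon_name].values
    lat = ds[lat_name].values
    lon, vals = _normalize_lon(lon, vals, lon_axis=2)
    attrs = {k: v for k, v in da.attrs.items() if k != "units"}
    return ClimateField(name=variable, units=str(da.attrs["units"]),
                        grid=Grid(lon=lon, lat=lat), times=da_t, values=vals, attrs=attrs)


# ---------------------------------------------------------------------------
# masks

def write_mask(mask: SurfaceTypeGrid, path) -> Path:
    path = Path(path)
    ds = xr.Dataset(
        {"mask": (("time", "lat", "lon"), mask.codes.astype(np.int32))},
        coords={"time": mask.epochs.astype(float), "lat": mask.grid.lat, "lon": mask.grid.lon},
    )
    ds["mask"].attrs.update({
        "units": "1",
        "flag_values": "0 1 2",
        "flag_meanings": " ".join(LEVEL_NAMES),
    })
    ds["time"].attrs.update(_TIME_ATTRS)
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_mask(path) -> SurfaceTypeGrid:
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds = ds.load()
    if "mask" not in ds:
        raise ValueError(f"{path}: no 'mask' variable")
    codes = ds["mask"].values
    codes3 = codes if codes.ndim == 3 else codes[None]
    lon, codes3 = _normalize_lon(ds["lon"].values, codes3, lon_axis=2)
    epochs = ds["time"].values if "time" in ds.coords else np.array([0])
    return SurfaceTypeGrid(
        grid=Grid(lon=lon, lat=ds["lat"].values),
        epochs=np.asarray(epochs).astype(int),
        codes=codes3.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# forcings (delimited text)

def write_forcings(table: ForcingTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False)
    return path


def read_forcings(path) -> ForcingTable:
    return ForcingTable.from_frame(pd.read_csv(Path(path)))


# ---------------------------------------------------------------------------
# snapshot sets

def write_snapshots(snapshots: SnapshotSet, directory) -> list:
    """One NetCDF per variable (epoch, month, lat, lon) plus the mask file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in snapshots.data.items():
        ds = xr.Dataset(
            {name: (("time", "month", "lat", "lon"), arr)},
            coords={"time": snapshots.epochs.astype(float),
                    "month": np.arange(13),
                    "lat": snapshots.grid.lat, "lon": snapshots.grid.lon},
        )
        from .grid import VARIABLE_UNITS
        ds[name].attrs["units"] = VARIABLE_UNITS.get(name, "1")
        ds["month"].attrs["long_name"] = "0-11 = Jan-Dec, 12 = annual mean"
        ds["time"].attrs.update(_TIME_ATTRS)
        p = directory / f"snapshots_{name}.nc"
        ds.to_netcdf(p, engine=_ENGINE)
        written.append(p)
    written.append(write_mask(snapshots.masks, directory / "snapshot_masks.nc"))
    return written


def read_snapshots(directory, variables=None) -> SnapshotSet:
    directory = Path(directory)
    masks = read_mask(directory / "snapshot_masks.nc")
    if variables is None:
        variables = sorted(p.stem.replace("snapshots_", "")
                           for p in directory.glob("snapshots_*.nc"))
    data = {}
    epochs = None
    for name in variables:
        with xr.open_dataset(directory / f"snapshots_{name}.nc", engine=_ENGINE) as ds:
            ds = ds.load()
        arr = ds[name].values
        lon, arr = _normalize_lon(ds["lon"].values, arr, lon_axis=3)
        data[name] = arr
        epochs = ds["time"].values.astype(int)
        grid = Grid(lon=lon, lat=ds["lat"].values)
    return SnapshotSet(grid=grid, epochs=epochs, data=data, masks=masks)


# ---------------------------------------------------------------------------
# reference climatologies

def write_reference(refs: dict, path) -> Path:
    """Write {month_index: ReferenceClimatology} of one variable to one file."""
    path = Path(path)
    months = sorted(refs)
    r0 = refs[months[0]]
    vals = np.stack([refs[m].values for m in months])
    valid = np.stack([refs[m].valid for m in months]).astype(np.int32)
    ds = xr.Dataset(
        {r0.name: (("month", "lat", "lon"), vals),
         "valid": (("month", "lat", "lon"), valid)},
        coords={"month": np.array(months), "lat": r0.grid.lat, "lon": r0.grid.lon},
    )
    ds[r0.name].attrs["units"] = r0.units
    ds["valid"].attrs["units"] = "1"
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_reference(path, variable: str | None = None) -> dict:
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds = ds.load()
    if variable is None:
        variable = next(v for v in ds.data_vars if v != "valid")
    vals = ds[variable].values
    valid = ds["valid"].values.astype(bool)
    lon, vals = _normalize_lon(ds["lon"].values, vals, lon_axis=2)
    _, valid = _normalize_lon(ds["lon"].values, valid, lon_axis=2)
    grid = Grid(lon=lon, lat=ds["lat"].values)
    return {
        int(m): ReferenceClimatology(
            name=variable, units=str(ds[variable].attrs["units"]), grid=grid,
            values=vals[k], valid=valid[k],
        )
        for k, m in enumerate(ds["month"].values)
    }


# ---------------------------------------------------------------------------
# emulator models

def write_emulator(model: EmulatorModel, path) -> Path:
    """Serialize a fitted emulator: one beta/p-value pair per coefficient,
    plus R^2/RMSE/mean-term grids, per variable, dims (month, lat, lon)."""
    path = Path(path)
    coords = {"month": np.arange(13), "lat": model.grid.lat, "lon": model.grid.lon,
              "level": np.arange(3)}
    data = {}
    attrs = {"training_epochs": json.dumps([int(e) for e in model.training_epochs]),
             "norm_mean": json.dumps(list(model.stats.mean)),
             "norm_std": json.dumps(list(model.stats.std)),
             "forcing_columns": " ".join(FORCING_COLUMNS)}
    for vname, vm in model.variables.items():
        for c, cname in enumerate(COEF_NAMES):
            data[f"{vname}_beta_{cname}"] = (("month", "lat", "lon"), vm.beta[..., c])
            data[f"{vname}_stderr_{cname}"] = (("month", "lat", "lon"), vm.stderr[..., c])
            data[f"{vname}_pvalue_{cname}"] = (("month", "lat", "lon"), vm.pvalues[..., c])
        data[f"{vname}_mean_term"] = (("month", "lat", "lon"), vm.mean_term)
        data[f"{vname}_r2"] = (("month", "lat", "lon"), vm.r2)
        data[f"{vname}_rmse"] = (("month", "lat", "lon"), vm.rmse)
        data[f"{vname}_fitted"] = (("month", "lat", "lon"), vm.fitted.astype(np.int32))
        attrs[f"{vname}_transform"] = vm.transform
    data["observed_levels"] = (("lat", "lon", "level"), model.observed_levels.astype(np.int32))
    ds = xr.Dataset(data, coords=coords, attrs=attrs)
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_emulator(path) -> EmulatorModel:
    with xr.open_dataset(Path(path), engine=_ENGINE) as ds:
        ds = ds.load()
    grid = Grid(lon=ds["lon"].values, lat=ds["lat"].values)
    stats = NormalizationStats(
        mean=np.array(json.loads(ds.attrs["norm_mean"])),
        std=np.array(json.loads(ds.attrs["norm_std"])),
    )
    training = np.array(json.loads(ds.attrs["training_epochs"]))
    vnames = sorted({k.rsplit("_transform", 1)[0] for k in ds.attrs if k.endswith("_transform")})
    variables = {}
    for vname in vnames:
        beta = np.stack([ds[f"{vname}_beta_{c}"].values for c in COEF_NAMES], axis=-1)
        se = np.stack([ds[f"{vname}_stderr_{c}"].values for c in COEF_NAMES], axis=-1)
        pv = np.stack([ds[f"{vname}_pvalue_{c}"].values for c in COEF_NAMES], axis=-1)
        variables[vname] = VariableModel(
            transform=str(ds.attrs[f"{vname}_transform"]),
            mean_term=ds[f"{vname}_mean_term"].values,
            beta=beta, stderr=se, pvalues=pv,
            r2=ds[f"{vname}_r2"].values, rmse=ds[f"{vname}_rmse"].values,
            fitted=ds[f"{vname}_fitted"].values.astype(bool),
        )
    return EmulatorModel(
        grid=grid, stats=stats, training_epochs=training, variables=variables,
        observed_levels=ds["observed_levels"].values.astype(bool),
    )
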