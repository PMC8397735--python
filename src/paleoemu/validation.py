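"""Technical validation: goodness maps, spatial covariance, proxy correlation.

Three independent checks of an emulated reconstruction:

* per-pixel R^2 (from the fit) and RMSE on held-out snapshot epochs;
* the pixel-by-pixel spatial covariance of the emulated fields over the
  snapshot epochs, compared with that of the original fields — a pixel-wise
  regression cannot impose spatial structure, so agreement here shows the
  structure survives emulation;
* Pearson (optionally Spearman) correlation between the emulated local time
  series and long proxy records at their core sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .emulator import ANNUAL, EmulatorModel, SnapshotSet, predict
from .forcings import ForcingTable
from .grid import ClimateField

__all__ = [
    "GoodnessMaps", "CovarianceSummary", "ProxyRecord",
    "goodness_maps", "spatial_covariance", "covariance_summary",
    "proxy_correlation", "proxy_table", "read_proxies",
]


@dataclass
class GoodnessMaps:
    """Per-pixel fit R^2 and held-out prediction RMSE, one pair per variable."""

    r2: dict    # variable -> (nlat, nlon), from fit diagnostics, training data
    rmse: dict  # variable -> (nlat, nlon), natural scale, test data
    month: int
    n_test_epochs: int


@dataclass
class CovarianceSummary:
    truth: np.ndarray
    emulated: np.ndarray
    difference: np.ndarray
    truth_norm: float
    diff_norm: float
    pixel_index: np.ndarray  # flattened (row-major lat x lon) indices included


@dataclass
class ProxyRecord:
    """An irregular proxy time series at a point location.

    ages in ka BP within [0, 800]; values in the proxy's own units (the
    correlation is unit-free, so no conversion is required).
    """

    name: str
    lon: float
    lat: float
    ages: np.ndarray
    values: np.ndarray
    kind: str = "SST"
    unit: str | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ValueError("ages and values must have equal length")
        if np.any((self.ages < 0) | (self.ages > 800)):
            raise ValueError("proxy ages must lie within 0-800 ka BP")
        if not (-90 <= self.lat <= 90):
            raise ValueError("latitude out of range")


def goodness_maps(
    model: EmulatorModel,
    test_snapshots: SnapshotSet,
    forcings: ForcingTable,
    month: int = ANNUAL,
) -> GoodnessMaps:
    """Fit R^2 plus natural-scale RMSE of predictions on held-out epochs."""
    test_epochs = np.asarray(test_snapshots.epochs)
    if test_epochs.size == 0:
        raise ValueError("test set is empty")
    if np.intersect1d(test_epochs, model.training_epochs).size:
        raise ValueError("test epochs overlap the training epochs")
    ftest = forcings.subset(forcings.index_of(test_epochs))

    r2 = {}
    rmse = {}
    for name, vm in model.variables.items():
        pred = predict(model, ftest, test_snapshots.masks, name, month=month)
        truth = test_snapshots.data[name][:, month]
        err = pred.values - truth
        rmse[name] = np.sqrt(np.nanmean(err**2, axis=0))
        rmse[name][~vm.fitted[month]] = np.nan
        r2[name] = vm.r2[month].copy()
    return GoodnessMaps(r2=r2, rmse=rmse, month=month, n_test_epochs=test_epochs.size)


def spatial_covariance(fields: ClimateField | np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Pixel x pixel covariance of per-pixel time series across epochs.

    fields: (nepochs, nlat, nlon) stack (or a ClimateField). Pixels are
    flattened row-major (lat, lon); with ``valid`` only those cells enter,
    so the matrix dimension equals the unmasked pixel count. Uses the
    unbiased (n-1) denominator.
    """
    values = fields.values if isinstance(fields, ClimateField) else np.asarray(fields, float)
    if values.ndim != 3:
        raise ValueError("expected a (nepochs, nlat, nlon) stack")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 epochs for a covariance")
    flat = values.reshape(n, -1)
    keep = np.asarray(valid, bool).ravel() if valid is not None else np.all(np.isfinite(flat), axis=0)
    return np.cov(flat[:, keep], rowvar=False, ddof=1)


def covariance_summary(truth: ClimateField, emulated: ClimateField) -> CovarianceSummary:
    """Covariance matrices of truth and emulation over common epochs, and
    their difference with Frobenius norms."""
    if not truth.grid.same_geometry(emulated.grid):
        raise ValueError("truth and emulated grids must match")
    common = np.intersect1d(truth.times, emulated.times)
    if common.size < 2:
        raise ValueError("need at least 2 common epochs")
    t_idx = [np.where(truth.times == t)[0][0] for t in common]
    e_idx = [np.where(emulated.times == t)[0][0] for t in common]
    tv = truth.values[t_idx]
    ev = emulated.values[e_idx]
    valid = np.all(np.isfinite(tv), axis=0) & np.all(np.isfinite(ev), axis=0)
    pixel_index = np.where(valid.ravel())[0]
    ct = np.cov(tv.reshape(len(common), -1)[:, pixel_index], rowvar=False, ddof=1)
    ce = np.cov(ev.reshape(len(common), -1)[:, pixel_index], rowvar=False, ddof=1)
    diff = ce - ct
    return CovarianceSummary(
        truth=ct, emulated=ce, difference=diff,
        truth_norm=float(np.linalg.norm(ct)), diff_norm=float(np.linalg.norm(diff)),
        pixel_index=pixel_index,
    )


def _cell_of(grid, lon: float, lat: float) -> tuple[int, int]:
    lon = ((lon + 180.0) % 360.0) - 180.0
    i = int(np.argmin(np.abs(grid.lat - lat)))
    dlon = np.abs((grid.lon - lon + 180.0) % 360.0 - 180.0)
    j = int(np.argmin(dlon))
    return i, j


def proxy_correlation(
    model_fields: ClimateField,
    proxy: ProxyRecord,
    max_age_offset: float = 0.5,
    method: str = "pearson",
) -> tuple[float, int]:
    """Correlation between the emulated local series and a proxy record.

    The model series is taken at the grid cell containing the proxy site;
    each proxy sample is paired with the nearest model epoch within
    ``max_age_offset`` ka (unmatched samples are dropped). Returns
    (correlation, number of pairs). Correlation is invariant to affine
    rescaling of the proxy, so records in arbitrary units compare directly.
    """
    i, j = _cell_of(model_fields.grid, proxy.lon, proxy.lat)
    series = model_fields.values[:, i, j]
    if not np.any(np.isfinite(series)):
        # point to the nearest cell with data
        finite = np.all(np.isfinite(model_fields.values), axis=0) | np.any(
            np.isfinite(model_fields.values), axis=0
        )
        cells = np.argwhere(finite)
        if cells.size:
            d = (model_fields.grid.lat[cells[:, 0]] - proxy.lat) ** 2 + (
                (model_fields.grid.lon[cells[:, 1]] - proxy.lon + 180) % 360 - 180
            ) ** 2
            ni, nj = cells[np.argmin(d)]
            hint = f"; nearest valid cell is (lat={model_fields.grid.lat[ni]:.2f}, " \
                   f"lon={model_fields.grid.lon[nj]:.2f})"
        else:
            hint = ""
        raise ValueError(f"proxy {proxy.name!r} falls on a masked cell{hint}")

    times = model_fields.times
    pairs_m, pairs_p = [], []
    for age, val in zip(proxy.ages, proxy.values):
        k = int(np.argmin(np.abs(times - age)))
        if abs(times[k] - age) <= max_age_offset and np.isfinite(series[k]) and np.isfinite(val):
            pairs_m.append(series[k])
            pairs_p.append(val)
    if len(pairs_m) < 3:
        raise ValueError(
            f"only {len(pairs_m)} matched points for proxy {proxy.name!r}; need >= 3"
        )
    if method == "spearman":
        r = sstats.spearmanr(pairs_m, pairs_p).statistic
    else:
        r = sstats.pearsonr(pairs_m, pairs_p).statistic
    return float(r), len(pairs_m)


def proxy_table(model_fields: ClimateField, proxies, **kw) -> pd.DataFrame:
    """Correlation table over a list of proxies (core, lon, lat, r, n, type)."""
    rows = []
    for p in proxies:
        try:
            r, n = proxy_correlation(model_fields, p, **kw)
        except ValueError:
            r, n = np.nan, 0
        rows.append({"core": p.name, "lon": p.lon, "lat": p.lat,
                     "corr_coeff": r, "n_matched": n, "type": p.kind})
    return pd.DataFrame(rows)


def read_proxies(path) -> list:
    """Read proxies from delimited text with columns
    name, lon, lat, age_ka, value [, type]."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"name", "lon", "lat", "age_ka", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"proxy file missing columns: {sorted(missing)}")
    out = []
    for name, g in df.groupby("name", sort=False):
        out.append(ProxyRecord(
            name=str(name), lon=float(g["lon"].iloc[0]), lat=float(g["lat"].iloc[0]),
            ages=g["age_ka"].to_numpy(), values=g["value"].to_numpy(),
            kind=str(g["type"].iloc[0]) if "type" in g else "unknown",
        ))
    return out
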