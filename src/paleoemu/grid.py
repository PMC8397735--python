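"""Regular lat/lon grid geometry and the gridded-field container.

All gridded quantities in the package live on a regular longitude/latitude
grid of cell centers. Longitudes are kept in [-180, 180); latitudes increase
south to north. Time axes are in ka BP (thousands of years before present),
positive into the past.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "ClimateField", "VARIABLE_UNITS"]

#: canonical units per climate variable
VARIABLE_UNITS = {
    "temperature": "K",
    "precipitation": "mm year-1",
    "cloud": "1",
}


@dataclass(frozen=True)
class Grid:
    """Regular grid of cell centers.

    Parameters
    ----------
    lon, lat : 1-D arrays of cell-center coordinates in degrees. Longitude
        must be equally spaced (treated as periodic in 360); latitude must
        be equally spaced and strictly monotonic.
    """

    lon: np.ndarray
    lat: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        for name, ax in (("lon", self.lon), ("lat", self.lat)):
            if ax.ndim != 1 or ax.size < 2:
                raise ValueError(f"{name} must be a 1-D axis with >= 2 points")
            steps = np.diff(ax)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-8 * max(1.0, abs(steps[0]))):
                raise ValueError(f"{name} must be equally spaced")

    @property
    def nlon(self) -> int:
        return self.lon.size

    @property
    def nlat(self) -> int:
        return self.lat.size

    @property
    def shape(self) -> tuple[int, int]:
        """(nlat, nlon) — the trailing array dimensions of every field."""
        return (self.nlat, self.nlon)

    @property
    def npixels(self) -> int:
        return self.nlat * self.nlon

    @property
    def dlon(self) -> float:
        return float(self.lon[1] - self.lon[0])

    @property
    def dlat(self) -> float:
        return float(self.lat[1] - self.lat[0])

    def pole_rows(self) -> np.ndarray:
        """Boolean latitude mask of rows at exactly 90 degrees N/S."""
        return np.isclose(np.abs(self.lat), 90.0)

    def same_geometry(self, other: "Grid", tol: float = 1e-8) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon, other.lon, atol=tol)
            and np.allclose(self.lat, other.lat, atol=tol)
        )

    @staticmethod
    def global_regular(nlon: int, nlat: int, include_poles: bool = False) -> "Grid":
        """A global grid with nlon x nlat cell centers.

        With ``include_poles`` the latitude axis runs exactly from -90 to 90
        (GCM-style, e.g. 96x73 at 3.75 x 2.5 degrees); otherwise centers are
        offset half a cell from the poles (obs-grid style, e.g. 720x360 at
        0.5 degrees with centers -89.75..89.75).
        """
        dlon = 360.0 / nlon
        lon = -180.0 + dlon * np.arange(nlon)
        if include_poles:
            lat = np.linspace(-90.0, 90.0, nlat)
        else:
            dlat = 180.0 / nlat
            lat = -90.0 + dlat * (np.arange(nlat) + 0.5)
        return Grid(lon=lon, lat=lat)


@dataclass
class ClimateField:
    """A gridded climate variable with a time axis and units metadata.

    values has shape (ntime, nlat, nlon); times are in ka BP. Missing or
    never-fit cells are NaN. Bounds (precipitation > 0, cloud in [0, 1])
    are part of the variable contract, checked by :meth:`check_bounds`.
    """

    name: str
    units: str
    grid: Grid
    times: np.ndarray
    values: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None, ...]
        expected = (self.times.size,) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (ntime, nlat, nlon) {expected}"
            )

    @property
    def ntime(self) -> int:
        return self.times.size

    def at_time(self, t: float) -> np.ndarray:
        idx = np.where(np.isclose(self.times, t))[0]
        if idx.size == 0:
            raise KeyError(f"epoch {t} ka BP not on the time axis")
        return self.values[idx[0]]

    def check_bounds(self) -> None:
        """Raise if finite values violate the variable's physical bounds."""
        v = self.values[np.isfinite(self.values)]
        if self.name.startswith("prec") and np.any(v < 0):
            raise ValueError("precipitation contains negative values")
        if self.name.startswith("cloud") or self.name.startswith("tcc"):
            if np.any((v < 0) | (v > 1)):
                raise ValueError("cloud cover outside [0, 1]")

    def copy_with(self, **kw) -> "ClimateField":
        base = dict(
            name=self.name, units=self.units, grid=self.grid,
            times=self.times.copy(), values=self.values.copy(), attrs=dict(self.attrs),
        )
        base.update(kw)
        return ClimateField(**base)
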