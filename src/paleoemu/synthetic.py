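"""Synthetic worlds with the statistical structure the emulator assumes.

A synthetic world is generated *from* the emulator's own model class: smooth
per-pixel true coefficient fields, quasi-periodic late-Pleistocene forcings
(CO2 saw-tooth in 180-300 ppm at ~100 ka, obliquity 22-24.5 degrees at ~41 ka,
precession indices within +-0.06 at ~21 ka), a sea-level- and ice-driven
surface-type history, and Gaussian noise on the regression scale. Because the
truth coefficients are stored, fits can be checked for exact recovery
(noiseless) and for confidence-interval coverage (noisy), and the full
pipeline can be closed end-to-end without any external data.

What this does not emulate: real atmospheric dynamics, spatially correlated
noise, or non-linear responses — agreement on a synthetic world validates the
machinery, not HadCM3 physics.

One global random stream per seed is split into named substreams (betas,
topography, noise, proxies, ...) so components stay independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .downscale import ReferenceClimatology, bilinear_regrid
from .emulator import (ANNUAL, N_COEF, SnapshotSet, VARIABLE_TRANSFORM,
                       inverse_transform)
from .forcings import ForcingTable, NormalizationStats, normalize_forcings, snapshot_epochs
from .grid import ClimateField, Grid, VARIABLE_UNITS
from .masks import LAND, LAND_ICE, OCEAN, SurfaceTypeGrid, build_surface_mask

__all__ = ["SyntheticWorld", "make_forcings", "make_world", "make_snapshots",
           "make_reference", "make_proxies", "truth_field", "extended_epochs"]

#: default per-variable noise standard deviation on the regression scale
DEFAULT_NOISE_SD = {"temperature": 0.2, "precipitation": 0.2, "cloud": 0.2}

#: spread of the true coefficient fields on the regression scale
BETA_SCALE = {"temperature": 1.0, "precipitation": 0.12, "cloud": 0.12}
SURFACE_SCALE = {"temperature": 2.0, "precipitation": 0.25, "cloud": 0.25}


def extended_epochs(n: int = 800) -> np.ndarray:
    """The hindcast epochs: n 1-ka steps ending at the present (n-1 ... 0 ka)."""
    return np.arange(n - 1, -1, -1)


# ---------------------------------------------------------------------------
# forcings

def _forcing_series(t: np.ndarray, seed: int):
    """Deterministic quasi-periodic forcing values at epochs t (ka BP)."""
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0, 2 * np.pi, size=3)
    t = np.asarray(t, dtype=float)
    # ~100 ka saw-tooth: slow glacial drawdown, rapid deglacial rise
    co2 = 300.0 - 120.0 * ((t % 100.0) / 100.0)
    obliquity = 23.25 + 1.25 * np.sin(2 * np.pi * t / 41.0 + ph[0])
    ecc = 0.03 + 0.025 * np.sin(2 * np.pi * t / 400.0 + ph[1])
    esinw = ecc * np.sin(2 * np.pi * t / 21.0 + ph[2])
    ecosw = ecc * np.cos(2 * np.pi * t / 21.0 + ph[2])
    return co2, obliquity, esinw, ecosw


def make_forcings(seed: int, epochs: np.ndarray | None = None) -> ForcingTable:
    """Forcing table at the 72 snapshot epochs (or any requested epochs).

    The same seed yields the same smooth series at any epoch set, so snapshot
    and extended tables are mutually consistent samples of one history.
    """
    if epochs is None:
        epochs = snapshot_epochs()
    co2, obl, esw, ecw = _forcing_series(np.asarray(epochs, float), seed)
    return ForcingTable(epochs=np.asarray(epochs), co2=co2, obliquity=obl,
                        precession_i=esw, precession_ii=ecw)


# ---------------------------------------------------------------------------
# the world

def _smooth_field(rng: np.random.Generator, grid: Grid, scale: float,
                  n_modes: int = 4) -> np.ndarray:
    """A smooth random field as a low-order Fourier sum, sd ~ scale."""
    lon = np.deg2rad(grid.lon)[None, :]
    lat = np.deg2rad(grid.lat)[:, None]
    out = np.zeros(grid.shape)
    for _ in range(n_modes):
        kx, ky = rng.integers(1, 4, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        out += rng.normal() * np.cos(kx * lon + px) * np.cos(ky * lat + py)
    sd = out.std()
    return out * (scale / sd if sd > 0 else 0.0)


@dataclass
class SyntheticWorld:
    grid: Grid
    seed: int
    forcings: ForcingTable                 # at the 72 snapshot epochs
    forcings_extended: ForcingTable        # 800 epochs ending at 0 ka
    stats: NormalizationStats              # z-scoring of the snapshot table
    true_beta: dict                        # var -> (13, nlat, nlon, 6)
    true_mean: dict                        # var -> (13, nlat, nlon), regression scale
    noise_sd: dict
    masks: SurfaceTypeGrid                 # over the union of all epochs
    topography: np.ndarray = field(repr=False, default=None)
    lakes: np.ndarray = field(repr=False, default=None)

    def masks_at(self, epochs) -> SurfaceTypeGrid:
        idx = np.array([np.where(self.masks.epochs == e)[0][0] for e in np.atleast_1d(epochs)])
        return self.masks.subset(idx)


def make_world(
    seed: int = 0,
    nlon: int = 12,
    nlat: int = 10,
    noise_sd: dict | float | None = None,
    include_poles: bool = False,
    n_extended: int = 800,
    variables: tuple = ("temperature", "precipitation", "cloud"),
) -> SyntheticWorld:
    """Build a complete synthetic world on an nlon x nlat coarse grid.

    The default 12x10 grid keeps every stage fast; pass nlon=96, nlat=73,
    include_poles=True for full-scale dimension checks.
    """
    grid = Grid.global_regular(nlon, nlat, include_poles=include_poles)
    if noise_sd is None:
        noise_sd = dict(DEFAULT_NOISE_SD)
    elif np.isscalar(noise_sd):
        noise_sd = {v: float(noise_sd) for v in variables}

    snap = make_forcings(seed)
    ext = make_forcings(seed, epochs=extended_epochs(n_extended))
    _, stats = normalize_forcings(snap)

    rng_beta = np.random.default_rng([seed, 1])
    rng_topo = np.random.default_rng([seed, 2])

    true_beta: dict[str, np.ndarray] = {}
    true_mean: dict[str, np.ndarray] = {}
    lat2d = np.repeat(grid.lat[:, None], grid.nlon, axis=1)
    base_mean = {
        "temperature": 300.0 - 35.0 * (np.abs(lat2d) / 90.0) ** 2,
        "precipitation": np.log(800.0) - 1.0 * (np.abs(lat2d) / 90.0),
        "cloud": np.zeros(grid.shape),
    }
    for var in variables:
        b = np.zeros((13,) + grid.shape + (N_COEF,))
        mu = np.zeros((13,) + grid.shape)
        bs, ss = BETA_SCALE[var], SURFACE_SCALE[var]
        for mi in range(13):
            for c in range(4):
                b[mi, :, :, c] = _smooth_field(rng_beta, grid, bs)
            b[mi, :, :, 4] = _smooth_field(rng_beta, grid, ss) + (ss if var == "temperature" else 0)
            b[mi, :, :, 5] = _smooth_field(rng_beta, grid, ss) - (2 * ss if var == "temperature" else 0)
            season = (np.cos(2 * np.pi * mi / 12.0) * np.sign(lat2d + 1e-9) * 3.0
                      if var == "temperature" and mi < 12 else 0.0)
            mu[mi] = base_mean[var] + _smooth_field(rng_beta, grid, bs) + season
        true_beta[var] = b
        true_mean[var] = mu

    # topography: smooth field shifted so ~40% of cells are below present sea level
    topo = _smooth_field(rng_topo, grid, 1000.0, n_modes=6)
    topo -= np.quantile(topo, 0.4)
    lakes = np.zeros(grid.shape, dtype=bool)
    land0 = topo > 0
    land_cells = np.argwhere(land0)
    if land_cells.size:
        pick = rng_topo.choice(len(land_cells), size=min(2, len(land_cells)), replace=False)
        for i, j in land_cells[pick]:
            lakes[i, j] = True

    all_epochs = np.union1d(snap.epochs, ext.epochs)[::-1]  # oldest first
    co2_all, _, _, _ = _forcing_series(all_epochs.astype(float), seed)
    codes = np.empty((all_epochs.size,) + grid.shape, dtype=np.int8)
    for k, (t, co2) in enumerate(zip(all_epochs, co2_all)):
        sea_level = co2 - 300.0                       # 0 m now, -120 m full glacial
        ice_lat = 75.0 - 20.0 * (300.0 - co2) / 120.0  # ice edge moves equatorward
        ocean_now = (topo <= sea_level) & ~lakes
        ice = (np.abs(lat2d) >= ice_lat) & ~ocean_now
        codes[k] = build_surface_mask(grid, topo, sea_level, ice, lakes).codes[0]
    masks = SurfaceTypeGrid(grid=grid, epochs=all_epochs, codes=codes)

    return SyntheticWorld(
        grid=grid, seed=seed, forcings=snap, forcings_extended=ext, stats=stats,
        true_beta=true_beta, true_mean=true_mean, noise_sd=noise_sd,
        masks=masks, topography=topo, lakes=lakes,
    )


# ---------------------------------------------------------------------------
# derived products

def _truth_transformed(world: SyntheticWorld, var: str, month: int,
                       table: ForcingTable) -> np.ndarray:
    """Noise-free regression-scale truth at the table's epochs."""
    Z = world.stats.apply(table.block())
    beta = world.true_beta[var][month]
    delta = np.einsum("tp,ijp->tij", Z, beta[:, :, :4])
    codes = world.masks_at(table.epochs).codes
    off = (np.where(codes == LAND, beta[None, :, :, 4], 0.0)
           + np.where(codes == LAND_ICE, beta[None, :, :, 5], 0.0))
    return world.true_mean[var][month][None] + delta + off


def truth_field(world: SyntheticWorld, var: str, month: int = ANNUAL,
                epochs: np.ndarray | None = None) -> ClimateField:
    """Noise-free natural-scale truth as a ClimateField."""
    table = world.forcings if epochs is None else make_forcings(
        world.seed, epochs=np.asarray(epochs))
    z = _truth_transformed(world, var, month, table)
    vals = inverse_transform(z, VARIABLE_TRANSFORM[var])
    return ClimateField(name=var, units=VARIABLE_UNITS[var], grid=world.grid,
                        times=table.epochs.astype(float), values=vals)


def make_snapshots(world: SyntheticWorld, noise: bool = True) -> SnapshotSet:
    """Snapshot climatologies at the 72 epochs: truth plus regression-scale
    Gaussian noise, inverse-transformed so all bounds hold by construction."""
    rng = np.random.default_rng([world.seed, 3])
    data = {}
    for var in world.true_beta:
        kind = VARIABLE_TRANSFORM[var]
        stack = np.empty((len(world.forcings), 13) + world.grid.shape)
        for mi in range(13):
            z = _truth_transformed(world, var, mi, world.forcings)
            if noise and world.noise_sd.get(var, 0) > 0:
                z = z + rng.normal(0.0, world.noise_sd[var], size=z.shape)
            stack[:, mi] = inverse_transform(z, kind)
        data[var] = stack
    return SnapshotSet(grid=world.grid, epochs=world.forcings.epochs,
                       data=data, masks=world.masks_at(world.forcings.epochs))


def fine_grid(world: SyntheticWorld, fine_factor: int) -> Grid:
    """A refinement of the coarse grid: same latitude span, factor x density."""
    g = world.grid
    dlon = 360.0 / (g.nlon * fine_factor)
    lon = -180.0 + dlon * np.arange(g.nlon * fine_factor)
    lat = np.linspace(g.lat[0], g.lat[-1], g.nlat * fine_factor)
    return Grid(lon=lon, lat=lat)


def make_reference(
    world: SyntheticWorld,
    fine_factor: int = 3,
    variable: str = "temperature",
    month: int = ANNUAL,
    bias_amplitude: float | None = None,
) -> ReferenceClimatology:
    """A fine-grid present-day reference: regridded epoch-0 truth plus a
    smooth synthetic observation bias, valid over land/ice cells only.

    Default bias amplitudes are typical GCM-vs-observation scales: 2 K for
    temperature, 50 mm/yr for precipitation, 0.05 for cloud fraction.
    """
    if fine_factor < 1 or int(fine_factor) != fine_factor:
        raise ValueError("fine_factor must be a positive integer")
    if bias_amplitude is None:
        bias_amplitude = {"temperature": 2.0, "precipitation": 50.0, "cloud": 0.05}[variable]
    fg = fine_grid(world, int(fine_factor))
    truth0 = truth_field(world, variable, month, epochs=np.array([0]))
    on_fine = bilinear_regrid(truth0, fg)
    rng = np.random.default_rng([world.seed, 4])
    bias = _smooth_field(rng, fg, bias_amplitude) if bias_amplitude > 0 else np.zeros(fg.shape)
    values = on_fine.values[0] + bias
    if variable == "precipitation":
        values = np.maximum(values, 0.1)
    elif variable == "cloud":
        values = np.clip(values, 1e-4, 1 - 1e-4)

    codes0 = world.masks_at([0]).codes[0]
    ii = np.array([np.argmin(np.abs(world.grid.lat - la)) for la in fg.lat])
    jj = np.array([np.argmin(np.abs((world.grid.lon - lo + 180) % 360 - 180)) for lo in fg.lon])
    valid = codes0[np.ix_(ii, jj)] != OCEAN
    return ReferenceClimatology(
        name=variable, units=VARIABLE_UNITS[variable], grid=fg,
        values=values, valid=valid,
    )


def make_proxies(world: SyntheticWorld, n: int, snr: float, seed: int,
                 affine: bool = False) -> list:
    """Synthetic proxy records at land sites.

    Each record samples the local noise-free annual temperature at irregular
    ages and adds white noise with sd = signal sd / snr. With ``affine`` the
    series is rescaled (a*x + b), mimicking non-temperature proxy units —
    which leaves the validation correlation unchanged.
    """
    from .validation import ProxyRecord
    if n < 1:
        raise ValueError("need n >= 1 proxies")
    rng = np.random.default_rng([world.seed, 5, seed])
    truth = truth_field(world, "temperature", ANNUAL, epochs=world.forcings_extended.epochs)
    codes0 = world.masks_at([0]).codes[0]
    land_cells = np.argwhere(codes0 == LAND)
    if land_cells.size == 0:
        raise RuntimeError("world has no land cells at the present epoch")
    picks = land_cells[rng.integers(0, len(land_cells), size=n)]
    out = []
    tmax = float(world.forcings_extended.epochs.max())
    for k, (i, j) in enumerate(picks):
        ages = np.sort(rng.uniform(0.0, tmax, size=rng.integers(60, 120)))
        series = truth.values[:, i, j]
        idx = np.array([np.argmin(np.abs(truth.times - a)) for a in ages])
        signal = series[idx]
        sd = signal.std() / snr if np.isfinite(snr) and snr > 0 else 0.0
        vals = signal + rng.normal(0, sd, size=signal.shape)
        if affine:
            vals = rng.uniform(0.5, 3.0) * vals + rng.uniform(-10, 10)
        out.append(ProxyRecord(
            name=f"SYN-{k:03d}", lon=float(world.grid.lon[j]), lat=float(world.grid.lat[i]),
            ages=ages, values=vals, kind="synthetic temperature",
        ))
    return out
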