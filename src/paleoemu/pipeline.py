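"""End-to-end pipeline: select -> fit -> predict -> downscale -> bias-correct
-> bioclim -> validate, chained through files in an output directory.

The pipeline consumes an input bundle (forcing tables, snapshot NetCDFs,
surface-type masks, fine-grid reference climatologies, proxy records) — which
the synthetic generator can write in full — and produces the product files
(temp_800ka_jan.nc ... bio19_800ka.nc), diagnostic tables, and a
machine-readable run manifest. The manifest contains only seed-deterministic
content (no wall-clock times), so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .bioclim import BIO_NAMES, compute_bioclim
from .downscale import bilinear_regrid, delta_correct
from .emulator import ANNUAL, MONTH_NAMES, fit_grid, predict
from .forcings import FORCING_COLUMNS
from .grid import ClimateField
from .selection import SelectionConfig, select_training
from .synthetic import make_reference, make_snapshots, make_world, make_proxies, truth_field
from .validation import covariance_summary, goodness_maps, proxy_table, read_proxies

__all__ = ["PipelineConfig", "run_pipeline", "ensure_bundle",
           "stage_select", "stage_fit", "stage_predict", "stage_correct",
           "stage_bioclim", "stage_validate"]

logger = logging.getLogger(__name__)

#: product-file short names per variable
SHORT_NAME = {"temperature": "temp", "precipitation": "prec", "cloud": "tcc"}


@dataclass
class PipelineConfig:
    outdir: str = "paleoemu_out"
    bundle_dir: str | None = None      # defaults to <outdir>/inputs
    seed: int = 0
    nlon: int = 12
    nlat: int = 10
    fine_factor: int = 3
    n_extended: int = 800
    noise_sd: float = 0.2
    train_fraction: float = 0.8
    n_iterations: int = 10_000
    variables: tuple = ("temperature", "precipitation", "cloud")
    months: tuple = tuple(range(13))
    delta_scale: str = "natural"
    correlation_method: str = "pearson"
    correlation_stage: str = "coarse"  # "coarse" (pre-correction) or "corrected"
    n_proxies: int = 8
    proxy_snr: float = 2.0

    def __post_init__(self):
        self.variables = tuple(self.variables)
        self.months = tuple(int(m) for m in self.months)

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    @property
    def bundle(self) -> Path:
        return Path(self.bundle_dir) if self.bundle_dir else self.out / "inputs"

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["variables"] = list(self.variables)
        d["months"] = list(self.months)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _timed(label: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            logger.info("stage %-12s %.2f s", label, time.perf_counter() - self.t0)
    return _T()


# ---------------------------------------------------------------------------
# bundle

def ensure_bundle(config: PipelineConfig) -> Path:
    """Generate the synthetic input bundle if it does not exist yet."""
    b = config.bundle
    if (b / "forcings_snapshots.csv").exists():
        return b
    b.mkdir(parents=True, exist_ok=True)
    with _timed("synth"):
        world = make_world(seed=config.seed, nlon=config.nlon, nlat=config.nlat,
                           noise_sd=config.noise_sd, n_extended=config.n_extended,
                           variables=config.variables)
        pio.write_forcings(world.forcings, b / "forcings_snapshots.csv")
        pio.write_forcings(world.forcings_extended, b / "forcings_extended.csv")
        pio.write_mask(world.masks, b / "masks_all.nc")
        snaps = make_snapshots(world)
        pio.write_snapshots(snaps, b)
        for var in config.variables:
            refs = {m: make_reference(world, config.fine_factor, variable=var, month=m)
                    for m in config.months}
            pio.write_reference(refs, b / f"reference_{var}.nc")
        proxies = make_proxies(world, n=config.n_proxies, snr=config.proxy_snr,
                               seed=config.seed)
        rows = []
        for p in proxies:
            for a, v in zip(p.ages, p.values):
                rows.append((p.name, p.lon, p.lat, a, v, p.kind))
        import pandas as pd
        pd.DataFrame(rows, columns=["name", "lon", "lat", "age_ka", "value", "type"]) \
            .to_csv(b / "proxies.csv", index=False)
        # noise-free truth at snapshot epochs for the covariance comparison
        tf = truth_field(world, "temperature", ANNUAL)
        pio.write_climate_netcdf(tf, b / "truth_temperature_ann.nc")
    return b


# ---------------------------------------------------------------------------
# stages

def stage_select(config: PipelineConfig) -> dict:
    """Training/test split of the snapshot epochs; writes JSON + counts table."""
    b = ensure_bundle(config)
    config.out.mkdir(parents=True, exist_ok=True)
    forc = pio.read_forcings(b / "forcings_snapshots.csv")
    sel = select_training(
        forc.block(),
        SelectionConfig(train_fraction=config.train_fraction,
                        n_iterations=config.n_iterations, seed=config.seed),
        epochs=forc.epochs,
    )
    out = {
        "train_epochs": [int(forc.epochs[i]) for i in sel.train_indices],
        "test_epochs": [int(forc.epochs[i]) for i in sel.test_indices],
        "candidate_count": int(sel.candidate_count),
    }
    with open(config.out / "selection.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    import pandas as pd
    pd.DataFrame({"epoch_ka": forc.epochs, "appearances": sel.appearance_counts}) \
        .to_csv(config.out / "selection_counts.tsv", sep="\t", index=False)
    return out


def _load_selection(config: PipelineConfig) -> dict:
    p = config.out / "selection.json"
    if not p.exists():
        return stage_select(config)
    with open(p) as fh:
        return json.load(fh)


def stage_fit(config: PipelineConfig, use_all_epochs: bool = True):
    """Fit the emulator and write it as NetCDF.

    The train/test split exists for validation; the production fit uses all
    snapshot epochs to exploit every available simulation (``use_all_epochs``).
    """
    b = ensure_bundle(config)
    snaps = pio.read_snapshots(b, variables=list(config.variables))
    forc = pio.read_forcings(b / "forcings_snapshots.csv")
    sel = _load_selection(config)
    train = snaps.epochs if use_all_epochs else np.array(sel["train_epochs"])
    with _timed("fit"):
        model = fit_grid(snaps, train, forc)
    pio.write_emulator(model, config.out / "emulator.nc")
    return model


def _load_model(config: PipelineConfig):
    p = config.out / "emulator.nc"
    return pio.read_emulator(p) if p.exists() else stage_fit(config)


def stage_predict(config: PipelineConfig) -> list:
    """Hindcast the coarse-grid fields over the extended epochs; one NetCDF
    per variable/month."""
    b = ensure_bundle(config)
    model = _load_model(config)
    ext = pio.read_forcings(b / "forcings_extended.csv")
    masks = pio.read_mask(b / "masks_all.nc")
    written = []
    with _timed("predict"):
        for var in config.variables:
            for m in config.months:
                fld = predict(model, ext, masks, var, month=m)
                written.append(pio.write_climate_netcdf(
                    fld, config.out / f"coarse_{SHORT_NAME[var]}_{MONTH_NAMES[m]}.nc"))
    return written


def stage_correct(config: PipelineConfig) -> list:
    """Bilinear downscaling plus delta bias correction; writes the
    <var>_800ka_<mon>.nc product files (and temp_800ka_min.nc)."""
    b = ensure_bundle(config)
    written = []
    monthly_temp_corr = {}
    with _timed("correct"):
        for var in config.variables:
            refs = pio.read_reference(b / f"reference_{var}.nc")
            for m in config.months:
                coarse = pio.read_climate_netcdf(
                    config.out / f"coarse_{SHORT_NAME[var]}_{MONTH_NAMES[m]}.nc")
                ref = refs[m]
                fine = bilinear_regrid(coarse, ref.grid)
                at0 = ClimateField(name=fine.name, units=fine.units, grid=fine.grid,
                                   times=np.array([0.0]), values=fine.at_time(0.0)[None])
                corr = delta_correct(fine, at0, ref, scale=config.delta_scale)
                # outside the reference's coverage keep the raw regridded field
                corr.values = np.where(ref.valid[None], corr.values, fine.values)
                corr.attrs["provenance"] = "1=bias-corrected, 0=raw regridded emulation"
                path = config.out / f"{SHORT_NAME[var]}_800ka_{MONTH_NAMES[m]}.nc"
                written.append(pio.write_climate_netcdf(corr, path))
                if var == "temperature" and m < 12:
                    monthly_temp_corr[m] = corr.values
        if len(monthly_temp_corr) == 12:
            sample = pio.read_climate_netcdf(config.out / "temp_800ka_jan.nc")
            tmin = np.min(np.stack([monthly_temp_corr[m] for m in range(12)]), axis=0)
            fld = ClimateField(name="tmin_ann", units="K", grid=sample.grid,
                               times=sample.times, values=tmin)
            written.append(pio.write_climate_netcdf(fld, config.out / "temp_800ka_min.nc"))
    return written


def stage_bioclim(config: PipelineConfig) -> list:
    """Bioclimatic variables from the corrected monthly products."""
    months_needed = set(range(12))
    if not months_needed <= set(config.months):
        logger.info("bioclim skipped: needs all 12 monthly fields")
        return []
    written = []
    with _timed("bioclim"):
        T = np.stack([pio.read_climate_netcdf(
            config.out / f"temp_800ka_{MONTH_NAMES[m]}.nc").values for m in range(12)])
        P = np.stack([pio.read_climate_netcdf(
            config.out / f"prec_800ka_{MONTH_NAMES[m]}.nc").values for m in range(12)])
        sample = pio.read_climate_netcdf(config.out / "temp_800ka_jan.nc")
        layers = compute_bioclim(T, P)
        units = {"bio12": "mm year-1", "bio13": "mm year-1", "bio14": "mm year-1",
                 "bio15": "1", "bio16": "mm year-1", "bio17": "mm year-1",
                 "bio18": "mm year-1", "bio19": "mm year-1"}
        for name in BIO_NAMES:
            fld = ClimateField(name=name, units=units.get(name, "degC"),
                               grid=sample.grid, times=sample.times, values=layers[name])
            written.append(pio.write_climate_netcdf(fld, config.out / f"{name}_800ka.nc"))
    return written


def stage_validate(config: PipelineConfig) -> dict:
    """Goodness maps on a held-out fit, covariance comparison, proxy table."""
    b = ensure_bundle(config)
    snaps = pio.read_snapshots(b, variables=list(config.variables))
    forc = pio.read_forcings(b / "forcings_snapshots.csv")
    sel = _load_selection(config)
    out: dict = {}
    with _timed("validate"):
        train = np.array(sel["train_epochs"])
        test = np.array(sel["test_epochs"])
        val_model = fit_grid(snaps, train, forc)
        test_snaps = snaps.subset(
            np.array([int(np.where(snaps.epochs == e)[0][0]) for e in test]))
        gm = goodness_maps(val_model, test_snaps, forc)
        for var in config.variables:
            ds_vals = {"r2": gm.r2[var], "rmse": gm.rmse[var]}
            for key, arr in ds_vals.items():
                fld = ClimateField(name=f"{key}", units="1", grid=val_model.grid,
                                   times=np.array([0.0]), values=arr[None])
                pio.write_climate_netcdf(
                    fld, config.out / f"goodness_{key}_{SHORT_NAME[var]}.nc")
            out[f"median_r2_{SHORT_NAME[var]}"] = float(np.nanmedian(gm.r2[var]))
            out[f"median_rmse_{SHORT_NAME[var]}"] = float(np.nanmedian(gm.rmse[var]))

        # spatial-covariance comparison against the stored truth fields
        truth = pio.read_climate_netcdf(b / "truth_temperature_ann.nc")
        masks = pio.read_mask(b / "masks_all.nc")
        model = _load_model(config)
        emu = predict(model, forc, masks, "temperature", month=ANNUAL)
        cs = covariance_summary(truth, emu)
        out["cov_truth_norm"] = cs.truth_norm
        out["cov_diff_norm"] = cs.diff_norm
        out["cov_dim"] = int(cs.truth.shape[0])

        # proxy correlations against the chosen reconstruction stage
        proxies = read_proxies(b / "proxies.csv")
        if config.correlation_stage == "corrected":
            series_field = pio.read_climate_netcdf(config.out / "temp_800ka_ann.nc")
        else:
            ext = pio.read_forcings(b / "forcings_extended.csv")
            series_field = predict(model, ext, masks, "temperature", month=ANNUAL)
        table = proxy_table(series_field, proxies, method=config.correlation_method)
        table.to_csv(config.out / "proxy_correlations.tsv", sep="\t", index=False)
        out["proxy_mean_corr"] = float(table["corr_coeff"].mean())
        out["proxy_n"] = int(len(table))
    with open(config.out / "validation_summary.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the run manifest; returns the manifest."""
    config.out.mkdir(parents=True, exist_ok=True)
    ensure_bundle(config)
    selection = stage_select(config)
    stage_fit(config)
    stage_predict(config)
    stage_correct(config)
    stage_bioclim(config)
    validation = stage_validate(config)

    from . import __version__
    files = sorted(p.name for p in config.out.iterdir() if p.is_file())
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "grid": {"coarse": [config.nlat, config.nlon],
                 "fine_factor": config.fine_factor,
                 "n_extended": config.n_extended},
        "n_train": len(selection["train_epochs"]),
        "n_test": len(selection["test_epochs"]),
        "candidate_count": selection["candidate_count"],
        "forcing_columns": list(FORCING_COLUMNS),
        "validation": validation,
        "files": files,
    }
    with open(config.out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
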