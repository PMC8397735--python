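"""Per-pixel linear emulation of GCM snapshot climatologies.

Each grid box x carries, for each month (Jan-Dec) and for the annual mean, a
linear regression of the transformed climate anomaly on the normalized
forcings plus a treatment-coded surface type:

    dY(x,t) = b1*d(obliquity) + b2*d(e sin w) + b3*d(e cos w) + b4*d(CO2)
              + b_surface[M(x,t)]

with ocean the reference level (offset fixed at 0) and dY the departure of
the transformed variable from its training-epoch mean. Temperature is fit on
the identity scale, precipitation on the log scale, cloud-cover fraction on
the logit scale, so that inverting the transform guarantees physical bounds
(precipitation > 0, cloud strictly inside (0, 1)) for any forcing input.

Snapshots are treated as independent equilibrium states: no temporal
autocorrelation enters the model. Pole rows (90 N/S) are never fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .forcings import ForcingTable, NormalizationStats, normalize_forcings
from .grid import ClimateField, Grid, VARIABLE_UNITS
from .masks import LAND, LAND_ICE, OCEAN, SurfaceTypeGrid

__all__ = [
    "VARIABLE_TRANSFORM", "MONTH_NAMES", "ANNUAL", "COEF_NAMES",
    "transform_values", "inverse_transform",
    "PixelModel", "VariableModel", "EmulatorModel", "SnapshotSet",
    "fit_pixel", "fit_grid", "predict",
]

logger = logging.getLogger(__name__)

VARIABLE_TRANSFORM = {
    "temperature": "identity",
    "precipitation": "log",
    "cloud": "logit",
}

MONTH_NAMES = ("jan", "feb", "mar", "apr", "may", "jun",
               "jul", "aug", "sep", "oct", "nov", "dec", "ann")
ANNUAL = 12  # month-axis index of the annual mean

#: coefficient order in the stored beta arrays
COEF_NAMES = ("obliquity", "precession_i", "precession_ii", "co2", "land", "land_ice")
N_COEF = len(COEF_NAMES)

#: precipitation values at or below zero are lifted to this floor (mm/year)
#: before the log transform; GCM output is never exactly zero but other
#: sources may be
PRECIP_FLOOR = 0.1


# ---------------------------------------------------------------------------
# transforms

def transform_values(values, kind: str, *, context: str = "") -> np.ndarray:
    """Map natural-scale values onto the unbounded regression scale."""
    v = np.asarray(values, dtype=float)
    where = f" ({context})" if context else ""
    if kind == "identity":
        return v.copy()
    if kind == "log":
        if np.any(v[np.isfinite(v)] <= 0):
            bad = int(np.sum(v[np.isfinite(v)] <= 0))
            raise ValueError(f"log transform requires positive values; {bad} violation(s){where}")
        return np.log(v)
    if kind == "logit":
        fin = v[np.isfinite(v)]
        if np.any((fin <= 0) | (fin >= 1)):
            bad = int(np.sum((fin <= 0) | (fin >= 1)))
            raise ValueError(f"logit transform requires values in (0,1); {bad} violation(s){where}")
        return np.log(v / (1.0 - v))
    raise ValueError(f"unknown transform kind {kind!r}")


def inverse_transform(values, kind: str) -> np.ndarray:
    """Map regression-scale values back to the natural scale.

    Defined on all reals; bounded variables come back strictly inside their
    bounds (exp > 0; the logistic is in (0, 1) exclusive).
    """
    z = np.asarray(values, dtype=float)
    if kind == "identity":
        return z.copy()
    if kind == "log":
        return np.exp(z)
    if kind == "logit":
        # numerically stable logistic
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    raise ValueError(f"unknown transform kind {kind!r}")


# ---------------------------------------------------------------------------
# containers

@dataclass
class PixelModel:
    """Fitted regression record for one (pixel, month, variable)."""

    transform: str
    mean_term: float
    beta: np.ndarray          # (6,) in COEF_NAMES order; NaN for absent levels
    stderr: np.ndarray        # (6,), NaN where not estimated
    pvalues: np.ndarray       # (6,), NaN where not estimated
    r2: float
    rmse: float               # residual RMSE on the transformed scale
    fitted_levels: tuple      # surface-type codes observed at this pixel
    ok: bool = True
    skip_reason: str | None = None

    @property
    def beta_orbital(self) -> np.ndarray:
        return self.beta[:3]

    @property
    def beta_co2(self) -> float:
        return float(self.beta[3])

    def beta_surface(self, level: int) -> float:
        if level == OCEAN:
            return 0.0
        return float(self.beta[3 + level])


@dataclass
class VariableModel:
    """All pixel models of one climate variable, as dense arrays.

    Arrays are shaped (13, nlat, nlon[, 6]); month index 12 is the annual
    mean. Unfit pixels (poles, rank-deficient designs) are NaN with
    ``fitted`` False and a reason string.
    """

    transform: str
    mean_term: np.ndarray
    beta: np.ndarray
    stderr: np.ndarray
    pvalues: np.ndarray
    r2: np.ndarray
    rmse: np.ndarray
    fitted: np.ndarray
    skip_reasons: dict = field(default_factory=dict)

    def pixel(self, month: int, i: int, j: int) -> PixelModel:
        key = (month, i, j)
        return PixelModel(
            transform=self.transform,
            mean_term=float(self.mean_term[month, i, j]),
            beta=self.beta[month, i, j].copy(),
            stderr=self.stderr[month, i, j].copy(),
            pvalues=self.pvalues[month, i, j].copy(),
            r2=float(self.r2[month, i, j]),
            rmse=float(self.rmse[month, i, j]),
            fitted_levels=tuple(np.where(~np.isnan(
                np.concatenate([[0.0], self.beta[month, i, j, 4:6]])
            ))[0]),
            ok=bool(self.fitted[month, i, j]),
            skip_reason=self.skip_reasons.get(key),
        )


@dataclass
class EmulatorModel:
    """Fitted emulator: one VariableModel per climate variable.

    Carries the grid geometry, the fit-time normalization statistics (which
    must be reused at prediction time), the training epochs, and the
    surface-type levels observed per pixel during training.
    """

    grid: Grid
    stats: NormalizationStats
    training_epochs: np.ndarray
    variables: dict  # name -> VariableModel
    observed_levels: np.ndarray  # (nlat, nlon, 3) bool

    @property
    def n_pixel_models(self) -> int:
        """Pixel-model slots per variable and month (= nlat * nlon)."""
        return self.grid.npixels


@dataclass
class SnapshotSet:
    """Stack of coarse-grid snapshot climatologies with surface-type grids.

    data maps variable name -> array (nepochs, 13, nlat, nlon) on the
    natural scale (month index 12 = annual mean).
    """

    grid: Grid
    epochs: np.ndarray
    data: dict
    masks: SurfaceTypeGrid

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        nexp = (self.epochs.size, 13) + self.grid.shape
        for name, arr in self.data.items():
            if arr.shape != nexp:
                raise ValueError(f"{name} shape {arr.shape} != {nexp}")
        if not np.array_equal(np.sort(self.masks.epochs), np.sort(self.epochs)):
            raise ValueError("mask epochs do not match snapshot epochs")

    def subset(self, indices) -> "SnapshotSet":
        idx = np.asarray(indices)
        mask_idx = np.array([np.where(self.masks.epochs == e)[0][0] for e in self.epochs[idx]])
        return SnapshotSet(
            grid=self.grid,
            epochs=self.epochs[idx],
            data={k: v[idx] for k, v in self.data.items()},
            masks=self.masks.subset(mask_idx),
        )


# ---------------------------------------------------------------------------
# fitting

def _design_matrix(zforcings: np.ndarray, levels: np.ndarray):
    """Intercept + forcings + treatment-coded dummies for the levels present.

    The reference level is ocean where observed, otherwise the lowest
    observed code, so the dummies never span the intercept. Returns
    (X, dummy_levels, ref_level); dummy columns exist only for observed
    non-reference levels, in ascending code order. The intercept is the
    reference level's offset and is folded into the stored mean term, which
    realizes treatment coding as a different intercept per surface type.
    """
    observed = sorted(int(l) for l in np.unique(levels))
    ref = OCEAN if OCEAN in observed else observed[0]
    n = len(levels)
    cols = [np.ones((n, 1)), zforcings]
    dummy_levels = []
    for lv in (LAND, LAND_ICE):
        if lv != ref and np.any(levels == lv):
            cols.append((levels == lv).astype(float)[:, None])
            dummy_levels.append(lv)
    return np.hstack(cols), dummy_levels, ref


def _ols(X: np.ndarray, Y: np.ndarray):
    """Least squares of anomaly columns Y (n, m) on design X (n, q).

    Returns (beta (q, m), stderr (q, m), pvalues (q, m), r2 (m,), rmse (m,),
    ok: bool). ok is False when X is rank deficient — callers flag those
    pixels unfit.
    """
    n, q = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        return None, None, None, None, None, False
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum(Y**2, axis=0)  # Y is already mean-removed
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    rmse = np.sqrt(ss_res / n)
    dof = n - q
    if dof > 0:
        sigma2 = ss_res / dof
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, 0.0)
        pvalues = 2.0 * sstats.t.sf(np.abs(tvals), dof)
        pvalues = np.where(se > 0, pvalues, 1.0)
    else:
        se = np.full_like(beta, np.nan)
        pvalues = np.full_like(beta, np.nan)
    return beta, se, pvalues, r2, rmse, True


def fit_pixel(y_series: np.ndarray, zforcings: np.ndarray, levels: np.ndarray,
              transform: str = "identity") -> PixelModel:
    """Fit one pixel's regression from transformed values at training epochs.

    y_series: (n,) values already on the regression scale; zforcings: (n, 4)
    normalized forcings; levels: (n,) surface-type codes at this pixel.
    The mean over training epochs is removed first and stored as the model's
    mean term; dummy columns exist only for levels actually observed.
    """
    y = np.asarray(y_series, dtype=float)
    n = y.size
    if n < 7:
        raise ValueError(f"need at least 7 training epochs, got {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y_series must be finite")
    mean_term = float(y.mean())
    X, dummy_levels, ref = _design_matrix(np.asarray(zforcings, float), np.asarray(levels))
    beta_full = np.full(N_COEF, np.nan)
    se_full = np.full(N_COEF, np.nan)
    pv_full = np.full(N_COEF, np.nan)
    observed = tuple(sorted(set(int(l) for l in np.unique(levels))))
    b, se, pv, r2, rmse, ok = _ols(X, (y - mean_term)[:, None])
    if not ok:
        return PixelModel(
            transform=transform, mean_term=mean_term, beta=beta_full,
            stderr=se_full, pvalues=pv_full, r2=np.nan, rmse=np.nan,
            fitted_levels=observed,
            ok=False, skip_reason="rank-deficient design after level pruning",
        )
    mean_term += float(b[0, 0])  # reference-level intercept
    beta_full[:4] = b[1:5, 0]
    se_full[:4] = se[1:5, 0]
    pv_full[:4] = pv[1:5, 0]
    if ref != OCEAN:
        beta_full[3 + ref] = 0.0
    for col, lv in enumerate(dummy_levels):
        beta_full[3 + lv] = b[5 + col, 0]
        se_full[3 + lv] = se[5 + col, 0]
        pv_full[3 + lv] = pv[5 + col, 0]
    return PixelModel(
        transform=transform, mean_term=mean_term, beta=beta_full,
        stderr=se_full, pvalues=pv_full, r2=float(r2[0]), rmse=float(rmse[0]),
        fitted_levels=observed,
    )


def _prepare_transformed(values: np.ndarray, name: str, transform: str) -> np.ndarray:
    """Transform a natural-scale stack, applying the precipitation floor."""
    v = np.asarray(values, dtype=float)
    if transform == "log":
        n_clamped = int(np.sum(v <= 0))
        if n_clamped:
            logger.warning("clamped %d non-positive precipitation value(s) to %.3g mm/yr",
                           n_clamped, PRECIP_FLOOR)
            v = np.maximum(v, PRECIP_FLOOR)
    return transform_values(v, transform, context=name)


def fit_grid(
    snapshots: SnapshotSet,
    training_epochs: np.ndarray,
    forcings: ForcingTable,
    stats: NormalizationStats | None = None,
) -> EmulatorModel:
    """Fit every non-pole pixel for each month and the annual mean.

    Normalization statistics default to the training-epoch forcings; pixels
    sharing a surface-type history share a design matrix and are solved in
    one batched least-squares call. Pole rows and rank-deficient pixels are
    flagged unfit and propagate as NaN.
    """
    training_epochs = np.asarray(training_epochs)
    snap_idx = {int(e): i for i, e in enumerate(snapshots.epochs)}
    missing = [int(e) for e in training_epochs if int(e) not in snap_idx]
    if missing:
        raise KeyError(f"training epochs missing from snapshots: {missing}")
    forcings.index_of(training_epochs)  # raises listing missing epochs

    train_table = forcings.subset(forcings.index_of(training_epochs))
    Z, stats = normalize_forcings(train_table, stats)

    grid = snapshots.grid
    nlat, nlon = grid.shape
    tr_rows = np.array([snap_idx[int(e)] for e in training_epochs])
    mask_rows = np.array(
        [np.where(snapshots.masks.epochs == e)[0][0] for e in training_epochs]
    )
    levels = snapshots.masks.codes[mask_rows]            # (ntr, nlat, nlon)
    levels_flat = levels.reshape(len(training_epochs), -1)

    pole = np.repeat(grid.pole_rows()[:, None], nlon, axis=1).ravel()
    observed = np.zeros((nlat * nlon, 3), dtype=bool)
    for lv in (OCEAN, LAND, LAND_ICE):
        observed[:, lv] = np.any(levels_flat == lv, axis=0)

    variables: dict[str, VariableModel] = {}
    for name, raw in snapshots.data.items():
        transform = VARIABLE_TRANSFORM.get(name, "identity")
        tr = _prepare_transformed(raw[tr_rows], name, transform)  # (ntr, 13, nlat, nlon)
        ntr = tr.shape[0]
        Yflat = tr.reshape(ntr, 13, -1)

        vm = VariableModel(
            transform=transform,
            mean_term=np.full((13, nlat, nlon), np.nan),
            beta=np.full((13, nlat, nlon, N_COEF), np.nan),
            stderr=np.full((13, nlat, nlon, N_COEF), np.nan),
            pvalues=np.full((13, nlat, nlon, N_COEF), np.nan),
            r2=np.full((13, nlat, nlon), np.nan),
            rmse=np.full((13, nlat, nlon), np.nan),
            fitted=np.zeros((13, nlat, nlon), dtype=bool),
        )
        mean_f = vm.mean_term.reshape(13, -1)
        beta_f = vm.beta.reshape(13, -1, N_COEF)
        se_f = vm.stderr.reshape(13, -1, N_COEF)
        pv_f = vm.pvalues.reshape(13, -1, N_COEF)
        r2_f = vm.r2.reshape(13, -1)
        rmse_f = vm.rmse.reshape(13, -1)
        fit_f = vm.fitted.reshape(13, -1)

        # group pixels by identical surface-type history: identical design
        keys = np.ascontiguousarray(levels_flat.T)
        _, inverse = np.unique(keys, axis=0, return_inverse=True)
        for g in np.unique(inverse):
            pix = np.where((inverse == g) & ~pole)[0]
            if pix.size == 0:
                continue
            lv_seq = levels_flat[:, pix[0]]
            X, dummy_levels, ref = _design_matrix(Z, lv_seq)
            Yg = Yflat[:, :, pix].reshape(ntr, -1)        # (ntr, 13*npix)
            mu = Yg.mean(axis=0)
            b, se, pv, r2, rmse, ok = _ols(X, Yg - mu)
            if not ok:
                mean_g = mu.reshape(13, pix.size)
                for mi in range(13):
                    mean_f[mi, pix] = mean_g[mi]
                for p in pix:
                    for mi in range(13):
                        vm.skip_reasons[(int(mi), int(p // nlon), int(p % nlon))] = (
                            "rank-deficient design after level pruning"
                        )
                continue
            b = b.reshape(-1, 13, pix.size)
            se = se.reshape(-1, 13, pix.size)
            pv = pv.reshape(-1, 13, pix.size)
            mean_f[:, pix] = mu.reshape(13, pix.size) + b[0]
            beta_f[:, pix, :4] = np.moveaxis(b[1:5], 0, -1)
            se_f[:, pix, :4] = np.moveaxis(se[1:5], 0, -1)
            pv_f[:, pix, :4] = np.moveaxis(pv[1:5], 0, -1)
            if ref != OCEAN:
                beta_f[:, pix, 3 + ref] = 0.0
            for col, lv in enumerate(dummy_levels):
                beta_f[:, pix, 3 + lv] = b[5 + col]
                se_f[:, pix, 3 + lv] = se[5 + col]
                pv_f[:, pix, 3 + lv] = pv[5 + col]
            r2_f[:, pix] = r2.reshape(13, pix.size)
            rmse_f[:, pix] = rmse.reshape(13, pix.size)
            fit_f[:, pix] = True

        for mi in range(13):
            for p in np.where(pole)[0]:
                vm.skip_reasons[(mi, int(p // nlon), int(p % nlon))] = "pole row excluded"
        variables[name] = vm

    return EmulatorModel(
        grid=grid, stats=stats, training_epochs=training_epochs,
        variables=variables, observed_levels=observed.reshape(nlat, nlon, 3),
    )


# ---------------------------------------------------------------------------
# prediction

def _surface_offsets(vm: VariableModel, month: int, codes: np.ndarray,
                     observed: np.ndarray) -> np.ndarray:
    """Per-epoch surface-type intercepts, substituting unfitted levels.

    Ocean is the reference (offset 0, always available). A land (resp. ice)
    cell whose pixel never saw land (ice) in training falls back to the
    other non-reference level if fitted, else to ocean; substitutions are
    counted and logged.
    """
    b_land = vm.beta[month, :, :, 4]
    b_ice = vm.beta[month, :, :, 5]
    land_ok = observed[:, :, LAND]
    ice_ok = observed[:, :, LAND_ICE]

    land_val = np.where(land_ok, b_land, np.where(ice_ok, b_ice, 0.0))
    ice_val = np.where(ice_ok, b_ice, np.where(land_ok, b_land, 0.0))
    n_sub = int(np.sum((codes == LAND) & ~land_ok) + np.sum((codes == LAND_ICE) & ~ice_ok))
    if n_sub:
        logger.warning("substituted nearest fitted surface level at %d cell-epoch(s)", n_sub)
    off = np.zeros(codes.shape, dtype=float)
    off += np.where(codes == LAND, land_val[None], 0.0)
    off += np.where(codes == LAND_ICE, ice_val[None], 0.0)
    return off


def predict(
    model: EmulatorModel,
    forcings: ForcingTable,
    masks: SurfaceTypeGrid,
    variable: str,
    month: int = ANNUAL,
    dtype=np.float64,
) -> ClimateField:
    """Hindcast one variable/month over the epochs of a forcing table.

    Forcings are z-scored with the model's fit-time statistics; the linear
    response plus surface-type offset and mean term is built on the
    regression scale, then inverse-transformed, so bounded variables are
    strictly within bounds. Unfit pixels are NaN.
    """
    if variable not in model.variables:
        raise KeyError(f"variable {variable!r} not in model")
    vm = model.variables[variable]
    Z = model.stats.apply(forcings.block())              # (nt, 4)
    mask_idx = np.array(
        [np.where(masks.epochs == e)[0][0] if np.any(masks.epochs == e) else -1
         for e in forcings.epochs]
    )
    if np.any(mask_idx < 0):
        bad = forcings.epochs[mask_idx < 0]
        raise KeyError(f"mask history missing epochs: {bad.tolist()}")
    codes = masks.codes[mask_idx]                        # (nt, nlat, nlon)

    beta4 = vm.beta[month, :, :, :4]                     # (nlat, nlon, 4)
    delta = np.einsum("tp,ijp->tij", Z, np.nan_to_num(beta4)).astype(dtype)
    delta += _surface_offsets(vm, month, codes, model.observed_levels).astype(dtype)
    ztrans = delta + vm.mean_term[month][None].astype(dtype)
    ztrans[:, ~vm.fitted[month]] = np.nan
    out = inverse_transform(ztrans, vm.transform).astype(dtype)

    return ClimateField(
        name=variable,
        units=VARIABLE_UNITS.get(variable, "1"),
        grid=model.grid,
        times=forcings.epochs.astype(float),
        values=out,
        attrs={"month": MONTH_NAMES[month], "transform": vm.transform},
    )
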