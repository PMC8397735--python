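"""Bilinear regridding to the fine reference grid and delta bias correction.

The coarse emulator output is first bilinearly interpolated to the reference
(observational) grid, then corrected additively: the cell-wise difference
between the reference climatology and the emulated present-day field is added
to every epoch. The additive "delta" leaves simulated anomalies between any
two epochs untouched and reproduces the reference exactly at the reference
epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import ClimateField, Grid

__all__ = ["ReferenceClimatology", "bilinear_regrid", "delta_correct", "bias_map"]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceClimatology:
    """Fine-grid reference (present-day observational) climatology.

    values (nlat, nlon) on the output grid; valid is the boolean cell mask
    (observations cover land only; invalid cells propagate as NaN through
    the correction).
    """

    name: str
    units: str
    grid: Grid
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for label, arr in (("values", self.values), ("valid", self.valid)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{label} shape {arr.shape} != grid {self.grid.shape}")


def _axis_weights(coarse: np.ndarray, fine: np.ndarray, periodic: bool):
    """Bracketing indices and weights of fine coordinates between coarse centers."""
    n = coarse.size
    if periodic:
        step = coarse[1] - coarse[0]
        rel = (fine - coarse[0]) / step
        i0 = np.floor(rel).astype(int)
        w = rel - i0
        return i0 % n, (i0 + 1) % n, w
    if np.any(fine < coarse[0] - 1e-9) or np.any(fine > coarse[-1] + 1e-9):
        raise ValueError(
            f"target latitude range [{fine.min():g}, {fine.max():g}] outside "
            f"coarse range [{coarse[0]:g}, {coarse[-1]:g}]"
        )
    i0 = np.clip(np.searchsorted(coarse, fine, side="right") - 1, 0, n - 2)
    w = (fine - coarse[i0]) / (coarse[i0 + 1] - coarse[i0])
    return i0, i0 + 1, np.clip(w, 0.0, 1.0)


def bilinear_regrid(coarse: ClimateField, target: Grid) -> ClimateField:
    """Interpolate a coarse field onto a finer grid with bilinear weights.

    Longitude is treated periodically; latitude must lie inside the coarse
    span. Where any of a fine cell's four coarse neighbours is missing, the
    nearest (highest-weight) valid neighbour value is used instead, so
    coastlines do not erode into NaN; fully-missing neighbourhoods stay NaN.
    """
    lat_sign = 1 if coarse.grid.dlat > 0 else -1
    clat = coarse.grid.lat[::lat_sign]
    j0, j1, wlat = _axis_weights(clat, target.lat, periodic=False)
    if lat_sign < 0:
        n = coarse.grid.nlat
        j0, j1 = n - 1 - j0, n - 1 - j1
    i0, i1, wlon = _axis_weights(coarse.grid.lon, target.lon, periodic=True)

    J0, I0 = np.meshgrid(j0, i0, indexing="ij")
    J1, I1 = np.meshgrid(j1, i1, indexing="ij")
    Wlat, Wlon = np.meshgrid(wlat, wlon, indexing="ij")
    w = np.stack([
        (1 - Wlat) * (1 - Wlon), (1 - Wlat) * Wlon,
        Wlat * (1 - Wlon), Wlat * Wlon,
    ])  # (4, nlat_f, nlon_f)

    out = np.empty((coarse.ntime,) + target.shape, dtype=coarse.values.dtype)
    for t in range(coarse.ntime):
        v = coarse.values[t]
        corners = np.stack([v[J0, I0], v[J0, I1], v[J1, I0], v[J1, I1]])
        nanmask = np.isnan(corners)
        if nanmask.any():
            wv = np.where(nanmask, -1.0, w)
            pick = np.argmax(wv, axis=0)
            nearest = np.take_along_axis(corners, pick[None], axis=0)[0]
            n_coastal = int((nanmask.any(axis=0) & ~nanmask.all(axis=0)).sum())
            if n_coastal:
                logger.debug("nearest-neighbour fallback at %d coastal fine cells", n_coastal)
            filled = np.where(nanmask, nearest[None], corners)
            out[t] = np.einsum("kij,kij->ij", w, filled)
        else:
            out[t] = np.einsum("kij,kij->ij", w, corners)

    return ClimateField(
        name=coarse.name, units=coarse.units, grid=target,
        times=coarse.times.copy(), values=out, attrs=dict(coarse.attrs),
    )


def _clamp(values: np.ndarray, name: str) -> np.ndarray:
    """Post-correction physical clamping for bounded variables, with counts."""
    if name.startswith("prec"):
        n = int(np.sum(values < 0))
        if n:
            logger.info("clamped %d negative precipitation value(s) to 0", n)
        return np.maximum(values, 0.0)
    if name.startswith("cloud") or name.startswith("tcc"):
        n = int(np.sum((values < 0) | (values > 1)))
        if n:
            logger.info("clamped %d cloud value(s) into [0, 1]", n)
        return np.clip(values, 0.0, 1.0)
    return values


def delta_correct(
    emulated: ClimateField,
    emulated_at_reference: ClimateField,
    reference: ReferenceClimatology,
    clamp: bool = True,
    scale: str = "natural",
) -> ClimateField:
    """Additive delta bias correction on the fine grid.

    corrected(x, t) = emulated(x, t) + [reference(x) - emulated(x, t_ref)]
    per cell and month. Cells invalid in the reference come back NaN. With
    ``clamp`` (default), bounded variables are clipped into their physical
    range afterwards; the pre-clamp field preserves anomalies exactly.

    scale="transformed" instead applies the delta on the variable's
    regression scale (log for precipitation, logit for cloud) and inverts,
    which keeps bounds without clamping; the default is the additive natural
    scale.
    """
    for other in (emulated_at_reference.grid, reference.grid):
        if not emulated.grid.same_geometry(other):
            raise ValueError("emulated, reference-epoch and reference grids must match")
    if emulated.units != reference.units:
        raise ValueError(
            f"unit mismatch: emulated {emulated.units!r} vs reference {reference.units!r}"
        )
    if scale == "transformed":
        from .emulator import VARIABLE_TRANSFORM, inverse_transform
        kind = VARIABLE_TRANSFORM.get(emulated.name, "identity")
        em = _safe_transform(emulated.values, kind)
        em0 = _safe_transform(emulated_at_reference.values[0], kind)
        ref = _safe_transform(reference.values, kind)
        corrected = inverse_transform(em + (ref - em0)[None], kind)
    else:
        # (em - em0) + ref rather than em + (ref - em0): the anomaly vanishes
        # identically at the reference epoch, so the correction reproduces
        # the reference climatology bit-for-bit there.
        anomaly = emulated.values - emulated_at_reference.values[0][None]
        corrected = anomaly + reference.values[None]
    corrected = np.where(reference.valid[None], corrected, np.nan)
    if clamp and scale == "natural":
        corrected = _clamp(corrected, emulated.name)
    return emulated.copy_with(values=corrected, attrs={**emulated.attrs, "bias_corrected": 1})


def _safe_transform(values: np.ndarray, kind: str) -> np.ndarray:
    """Transform, mapping out-of-domain values to NaN instead of raising."""
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if kind == "log":
            return np.log(np.where(v > 0, v, np.nan))
        if kind == "logit":
            v = np.where((v > 0) & (v < 1), v, np.nan)
            return np.log(v / (1 - v))
    return v.copy()


def bias_map(
    emulated_at_reference: ClimateField, reference: ReferenceClimatology
) -> ClimateField:
    """Model bias: emulated present-day field minus the reference, per cell."""
    if not emulated_at_reference.grid.same_geometry(reference.grid):
        raise ValueError("grids must match")
    diff = emulated_at_reference.values[0] - reference.values
    diff = np.where(reference.valid, diff, np.nan)
    return emulated_at_reference.copy_with(
        values=diff[None],
        name=f"{emulated_at_reference.name}_bias",
        attrs={**emulated_at_reference.attrs, "kind": "model bias vs reference"},
    )
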