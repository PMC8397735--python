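"""Categorical surface-type grids: ocean, land, land ice.

Surface type enters the regression as a treatment-coded categorical predictor
with ocean as the reference level. Masks change through time with sea level
(coastline migration) and ice-sheet extent; inland lakes keep their
present-day class regardless of the sea-level offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import Grid

__all__ = [
    "OCEAN", "LAND", "LAND_ICE", "LEVEL_NAMES",
    "SurfaceTypeGrid", "build_surface_mask",
]

logger = logging.getLogger(__name__)

OCEAN, LAND, LAND_ICE = 0, 1, 2
LEVEL_NAMES = ("ocean", "land", "land_ice")


@dataclass
class SurfaceTypeGrid:
    """Per-epoch categorical surface-type grids on a fixed geometry.

    codes has shape (nepochs, nlat, nlon) with integer levels
    0=ocean, 1=land, 2=land_ice.
    """

    grid: Grid
    epochs: np.ndarray
    codes: np.ndarray

    def __post_init__(self):
        self.epochs = np.atleast_1d(np.asarray(self.epochs))
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim == 2:
            self.codes = self.codes[None, ...]
        expected = (self.epochs.size,) + self.grid.shape
        if self.codes.shape != expected:
            raise ValueError(f"codes shape {self.codes.shape} != {expected}")
        if not np.isin(self.codes, (OCEAN, LAND, LAND_ICE)).all():
            raise ValueError("mask codes must be 0 (ocean), 1 (land) or 2 (land_ice)")

    def at_epoch(self, t) -> np.ndarray:
        idx = np.where(self.epochs == t)[0]
        if idx.size == 0:
            raise KeyError(f"epoch {t} ka not in mask history")
        return self.codes[idx[0]]

    def subset(self, indices) -> "SurfaceTypeGrid":
        idx = np.asarray(indices)
        return SurfaceTypeGrid(grid=self.grid, epochs=self.epochs[idx], codes=self.codes[idx])

    def level_counts(self) -> np.ndarray:
        """(nepochs, 3) counts of ocean/land/land_ice cells per epoch."""
        return np.stack(
            [(self.codes == lv).sum(axis=(1, 2)) for lv in (OCEAN, LAND, LAND_ICE)], axis=1
        )


def build_surface_mask(
    grid: Grid,
    topography: np.ndarray,
    sea_level: float,
    ice_extent: np.ndarray,
    lakes: np.ndarray | None = None,
) -> SurfaceTypeGrid:
    """Classify every cell as ocean, land, or land ice for one epoch.

    Rules, in order:

    1. lake cells keep their present-day class (land if above present sea
       level, ocean otherwise) — inland lakes are preserved through time;
    2. remaining cells with elevation <= sea_level become ocean;
    3. remaining cells under ice_extent become land ice — ice converts land,
       never ocean (ice flagged over an ocean cell is dropped with a warning);
    4. everything else is land.

    Parameters
    ----------
    topography : elevation in metres relative to present sea level.
    sea_level : sea-level offset in metres (negative during glacials).
    ice_extent, lakes : boolean grids on the same geometry.
    """
    topography = np.asarray(topography, dtype=float)
    ice_extent = np.asarray(ice_extent, dtype=bool)
    if lakes is None:
        lakes = np.zeros(grid.shape, dtype=bool)
    lakes = np.asarray(lakes, dtype=bool)
    for name, arr in (("topography", topography), ("ice_extent", ice_extent), ("lakes", lakes)):
        if arr.shape != grid.shape:
            raise ValueError(f"{name} shape {arr.shape} does not match grid {grid.shape}")

    codes = np.full(grid.shape, LAND, dtype=np.int8)
    ocean = (topography <= sea_level) & ~lakes
    codes[ocean] = OCEAN
    ice_on_ocean = ice_extent & ocean
    if ice_on_ocean.any():
        logger.warning(
            "dropping ice flagged over %d ocean cell(s); ice never overrides ocean",
            int(ice_on_ocean.sum()),
        )
    codes[ice_extent & ~ocean & ~lakes] = LAND_ICE
    # present-day class for preserved lakes: the sea_level = 0 land/ocean rule
    codes[lakes & (topography <= 0)] = OCEAN
    codes[lakes & (topography > 0)] = LAND
    return SurfaceTypeGrid(grid=grid, epochs=np.array([0]), codes=codes[None, ...])
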