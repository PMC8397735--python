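"""External forcings: CO2, obliquity, and the two precession indices.

The emulator's continuous predictors are atmospheric CO2 (ppm), obliquity
(degrees), and the precession indices e*sin(omega) and e*cos(omega). Epochs
are integer ka BP, positive into the past, present = 0. Predictors are
z-scored before fitting; the fit-time statistics must be reused verbatim at
prediction time, so they travel with the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FORCING_COLUMNS",
    "ForcingTable",
    "NormalizationStats",
    "interpolate_co2",
    "normalize_forcings",
    "snapshot_epochs",
]

#: column order of the continuous predictor block
FORCING_COLUMNS = ("obliquity", "precession_i", "precession_ii", "co2")


def snapshot_epochs() -> np.ndarray:
    """The 72 snapshot epochs: 120-24 ka at 2 ka steps, 22-0 ka at 1 ka steps.

    Returned oldest first (descending ka BP).
    """
    return np.concatenate([np.arange(120, 23, -2), np.arange(22, -1, -1)])


@dataclass
class ForcingTable:
    """Per-epoch forcing values.

    epochs: integer ka BP, strictly monotonic (any direction).
    co2 in ppm (> 0); obliquity in degrees; precession indices dimensionless.
    """

    epochs: np.ndarray
    co2: np.ndarray
    obliquity: np.ndarray
    precession_i: np.ndarray
    precession_ii: np.ndarray

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        for col in FORCING_COLUMNS:
            setattr(self, col, np.asarray(getattr(self, col), dtype=float))
        n = self.epochs.size
        for col in FORCING_COLUMNS:
            if getattr(self, col).shape != (n,):
                raise ValueError(f"column {col!r} length != number of epochs")
        d = np.diff(self.epochs.astype(float))
        if n > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("epochs must be strictly monotonic")
        if np.any(self.co2 <= 0):
            raise ValueError("co2 must be positive everywhere")
        block = self.block()
        if not np.all(np.isfinite(block)):
            raise ValueError("forcing columns must be finite")

    def __len__(self) -> int:
        return int(self.epochs.size)

    def block(self) -> np.ndarray:
        """(n, 4) predictor matrix in FORCING_COLUMNS order."""
        return np.column_stack([getattr(self, c) for c in FORCING_COLUMNS])

    def subset(self, indices) -> "ForcingTable":
        idx = np.asarray(indices)
        return ForcingTable(
            epochs=self.epochs[idx],
            co2=self.co2[idx],
            obliquity=self.obliquity[idx],
            precession_i=self.precession_i[idx],
            precession_ii=self.precession_ii[idx],
        )

    def index_of(self, epochs) -> np.ndarray:
        """Positions of the given epochs in the table; error if any missing."""
        pos = {int(e): i for i, e in enumerate(self.epochs)}
        missing = [int(e) for e in np.atleast_1d(epochs) if int(e) not in pos]
        if missing:
            raise KeyError(f"epochs missing from forcing table: {missing}")
        return np.array([pos[int(e)] for e in np.atleast_1d(epochs)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_ka": self.epochs, **{c: getattr(self, c) for c in FORCING_COLUMNS}}
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ForcingTable":
        return ForcingTable(
            epochs=df["epoch_ka"].to_numpy(),
            co2=df["co2"].to_numpy(),
            obliquity=df["obliquity"].to_numpy(),
            precession_i=df["precession_i"].to_numpy(),
            precession_ii=df["precession_ii"].to_numpy(),
        )


@dataclass(frozen=True)
class NormalizationStats:
    """Per-forcing mean and standard deviation used for z-scoring."""

    mean: np.ndarray  # (4,) in FORCING_COLUMNS order
    std: np.ndarray   # (4,), all > 0

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if np.any(self.std <= 0):
            raise ValueError("every standard deviation must be > 0")

    def apply(self, block: np.ndarray) -> np.ndarray:
        return (block - self.mean) / self.std

    def invert(self, zblock: np.ndarray) -> np.ndarray:
        return zblock * self.std + self.mean


def interpolate_co2(raw_epochs, raw_ppm, target_epochs) -> np.ndarray:
    """Piecewise-linear interpolation of an irregular CO2 record.

    Values at raw sample times are reproduced exactly; requests outside the
    raw record's span are an error (no extrapolation).
    """
    raw_epochs = np.asarray(raw_epochs, dtype=float)
    raw_ppm = np.asarray(raw_ppm, dtype=float)
    target = np.asarray(target_epochs, dtype=float)
    order = np.argsort(raw_epochs)
    xs, ys = raw_epochs[order], raw_ppm[order]
    lo, hi = xs[0], xs[-1]
    out_lo, out_hi = target.min(), target.max()
    if out_lo < lo or out_hi > hi:
        raise ValueError(
            f"CO2 record covers [{lo:g}, {hi:g}] ka but epochs request "
            f"[{out_lo:g}, {out_hi:g}] ka; cannot extrapolate"
        )
    return np.interp(target, xs, ys)


def normalize_forcings(
    table: ForcingTable, stats: NormalizationStats | None = None
) -> tuple[np.ndarray, NormalizationStats]:
    """Z-score the continuous predictor block.

    With ``stats`` absent the statistics are computed from ``table`` (each
    output column then has mean 0, sd 1) and returned for reuse; with
    ``stats`` supplied the given transform is applied unchanged, as required
    at prediction time.
    """
    block = table.block()
    if stats is None:
        mean = block.mean(axis=0)
        std = block.std(axis=0, ddof=0)
        dead = np.where(std <= 0)[0]
        if dead.size:
            names = [FORCING_COLUMNS[i] for i in dead]
            raise ValueError(f"zero-variance forcing column(s): {names}")
        stats = NormalizationStats(mean=mean, std=std)
    return stats.apply(block), stats
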