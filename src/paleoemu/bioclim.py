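"""Bioclimatic variables (BIO1, BIO4-BIO19) from monthly temperature and
precipitation.

BIO2 (mean diurnal range) and BIO3 (isothermality) require monthly minimum
and maximum temperatures, which monthly-mean climatologies do not carry; they
are deliberately never produced, leaving 17 layers. In addition the minimum
annual temperature (coldest monthly mean, in K) is emitted as a plain
climatic variable.

Conventions:

* temperatures enter in K and leave in degrees C (except minimum annual
  temperature, kept in K);
* monthly precipitation enters as a rate in mm/year; BIO12 is the annual
  mean rate, and per-month/per-quarter totals (BIO13/14, BIO16-19) convert
  the rate uniformly at 1/12 per month;
* a quarter is any of the 12 consecutive 3-month windows with Dec-Jan
  wrap-around; ties select the earliest window;
* BIO4 is the population standard deviation of the 12 monthly temperatures
  in degrees C (no x100 scaling); BIO15 is 100 * sd / mean of monthly
  precipitation, defined as 0 where the mean is 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BIO_NAMES", "quarter_stat", "compute_bioclim", "K_TO_C"]

K_TO_C = 273.15

BIO_NAMES = (
    "bio01", "bio04", "bio05", "bio06", "bio07", "bio08", "bio09", "bio10",
    "bio11", "bio12", "bio13", "bio14", "bio15", "bio16", "bio17", "bio18",
    "bio19",
)

_MODES = {"wettest": np.argmax, "driest": np.argmin,
          "warmest": np.argmax, "coldest": np.argmin}


def _quarter_sums(monthly: np.ndarray) -> np.ndarray:
    """(12, ...) sums of the 12 wrap-around 3-month windows starting at each month."""
    m = np.asarray(monthly, dtype=float)
    return np.stack([m[i % 12] + m[(i + 1) % 12] + m[(i + 2) % 12] for i in range(12)])


def quarter_stat(selector_monthly, mode: str, companion_monthly, stat: str = "mean"):
    """Select the extremal 3-month window of a selector series and summarize a
    companion series over it.

    selector_monthly, companion_monthly: arrays with a leading month axis of
    length 12 (Dec-Jan wrap-around allowed). The window is chosen by the
    extremal *sum* of the selector; ``np.argmax``/``argmin`` tie-breaking
    picks the earliest window. Returns (start-month index array, the mean or
    total of the companion over that window).
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}")
    sel = np.asarray(selector_monthly, dtype=float)
    comp = np.asarray(companion_monthly, dtype=float)
    if sel.shape[0] != 12 or comp.shape[0] != 12:
        raise ValueError("monthly inputs need a leading axis of length 12")
    qsel = _quarter_sums(sel)
    idx = _MODES[mode](qsel, axis=0)
    qcomp = _quarter_sums(comp)
    total = np.take_along_axis(qcomp, idx[None], axis=0)[0]
    value = total / 3.0 if stat == "mean" else total
    return idx, value


def compute_bioclim(monthly_T: np.ndarray, monthly_P: np.ndarray) -> dict:
    """All 17 BIO layers plus minimum annual temperature.

    monthly_T in K, monthly_P in mm/year, both with a leading month axis of
    length 12 (any trailing shape: scalar series, (lat, lon), or
    (time, lat, lon)). Returns a dict of arrays keyed 'bio01'...'bio19' plus
    'tmin_ann' (K); bio02/bio03 are never present.
    """
    T = np.asarray(monthly_T, dtype=float)
    P = np.asarray(monthly_P, dtype=float)
    for name, arr in (("monthly_T", T), ("monthly_P", P)):
        if arr.shape[0] != 12:
            raise ValueError(f"{name} must have 12 months on the leading axis, got {arr.shape[0]}")
    if T.shape != P.shape:
        raise ValueError("temperature and precipitation shapes must match")

    Tc = T - K_TO_C
    out: dict[str, np.ndarray] = {}
    out["bio01"] = Tc.mean(axis=0)
    out["bio04"] = Tc.std(axis=0, ddof=0)
    out["bio05"] = Tc.max(axis=0)
    out["bio06"] = Tc.min(axis=0)
    out["bio07"] = out["bio05"] - out["bio06"]
    _, out["bio08"] = quarter_stat(P, "wettest", Tc, stat="mean")
    _, out["bio09"] = quarter_stat(P, "driest", Tc, stat="mean")
    _, out["bio10"] = quarter_stat(Tc, "warmest", Tc, stat="mean")
    _, out["bio11"] = quarter_stat(Tc, "coldest", Tc, stat="mean")

    out["bio12"] = P.mean(axis=0)  # annual total expressed as the mean rate, mm/year
    Pm = P / 12.0                  # per-month totals from the annual rate
    out["bio13"] = Pm.max(axis=0)
    out["bio14"] = Pm.min(axis=0)
    mean_p = P.mean(axis=0)
    sd_p = P.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean_p > 0, 100.0 * sd_p / mean_p, 0.0)
    out["bio15"] = cv
    _, out["bio16"] = quarter_stat(Pm, "wettest", Pm, stat="total")
    _, out["bio17"] = quarter_stat(Pm, "driest", Pm, stat="total")
    _, out["bio18"] = quarter_stat(Tc, "warmest", Pm, stat="total")
    _, out["bio19"] = quarter_stat(Tc, "coldest", Pm, stat="total")

    out["tmin_ann"] = T.min(axis=0)
    return out
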