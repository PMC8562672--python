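"""Kinetics of the collagen lattice periods under sugar incubation.

Both the equatorial spacing d_E and the meridional period d_M drift as
glycation proceeds; empirically the *squared relative variation*
``(d_t/d_0 - 1)**2`` grows linearly with incubation time for both ribose
and glucose, with sugar-specific slopes.  This module turns tabulated
per-timepoint observables into those linear laws, the ribose/glucose time
scale factor f, the electron-density-contrast trend, and the first-order
fibril volume change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LatticeTimeSeries",
    "SlopeFit",
    "load_timeseries",
    "load_table",
    "squared_rel_variation",
    "fit_linear",
    "fit_period_law",
    "slope_ratio",
    "delta_rho_trend",
    "delta_rho_increment",
    "volume_change",
]

_COLUMNS = ["t_days", "d_M", "d_M_err", "d_E", "d_E_err",
            "delta_rho", "delta_rho_err", "sugar", "concentration"]


@dataclass
class LatticeTimeSeries:
    """Per-timepoint lattice observables for one sugar/concentration series."""

    data: pd.DataFrame
    sugar: str = ""
    concentration: float = float("nan")

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS[:7] if c not in self.data.columns]
        if missing:
            raise ValueError(f"time series missing columns {missing}")
        t = self.data["t_days"].to_numpy(dtype=float)
        if t.size < 2 or t[0] != 0:
            raise ValueError("series must start at t=0 (baseline row)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.data["t_days"].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)


@dataclass
class SlopeFit:
    """An OLS line fit with the sign convention used for period drifts.

    ``slope`` carries the sign of the underlying raw period change (the
    fitted quantity, a squared variation, is nonnegative); ``sign`` is that
    convention factor (+1 growing, -1 shrinking).
    """

    slope: float
    intercept: float
    stderr_slope: float
    r_squared: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.stderr_slope < 0:
            raise ValueError("stderr must be nonnegative")

    @property
    def magnitude(self) -> float:
        return abs(self.slope)


def load_timeseries(path: str | Path) -> LatticeTimeSeries:
    """Read a lattice time-series CSV (schema: t_days,d_M,d_M_err,...)."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sugar = str(df["sugar"].iloc[0]) if "sugar" in df.columns else ""
    conc = float(df["concentration"].iloc[0]) if "concentration" in df.columns else float("nan")
    return LatticeTimeSeries(df, sugar=sugar, concentration=conc)


def load_table(which: str) -> LatticeTimeSeries:
    """Packaged observable tables: 'ribose' (40 mg/ml) or 'glucose' (40 mg/ml)."""
    names = {"ribose": "table1_ribose.csv", "glucose": "table2_glucose.csv"}
    if which not in names:
        raise ValueError(f"which must be one of {sorted(names)}")
    src = resources.files("glycofibril.data").joinpath(names[which])
    with resources.as_file(src) as p:
        return load_timeseries(p)


def squared_rel_variation(series: LatticeTimeSeries, field: str) -> tuple[np.ndarray, np.ndarray]:
    """(t, y) with y(t) = (field_t / field_0 - 1)**2; y(0) = 0 exactly."""
    if field not in ("d_E", "d_M"):
        raise ValueError("field must be 'd_E' or 'd_M'")
    v = series.column(field)
    y = (v / v[0] - 1.0) ** 2
    y[0] = 0.0
    return series.t, y


def fit_linear(t: np.ndarray, y: np.ndarray, sign: int | None = None,
               through_origin: bool = False) -> SlopeFit:
    """OLS line fit of y against t (with intercept by default).

    When ``sign`` is given it restores the direction of the underlying raw
    change (a squared variation cannot carry it) and the returned slope is
    sign * |fitted slope|; otherwise the raw fitted slope is reported.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: all t equal")
    if through_origin:
        slope = float(np.sum(t * y) / np.sum(t * t))
        resid = y - slope * t
        dof = max(t.size - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / np.sum(t * t)))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        intercept = 0.0
    else:
        res = stats.linregress(t, y)
        slope, intercept = float(res.slope), float(res.intercept)
        stderr, r2 = float(res.stderr), float(res.rvalue**2)
    if sign is None:
        return SlopeFit(slope=slope, intercept=intercept, stderr_slope=stderr,
                        r_squared=r2, sign=1 if slope >= 0 else -1)
    return SlopeFit(slope=sign * abs(slope), intercept=intercept,
                    stderr_slope=stderr, r_squared=r2, sign=sign)


def fit_period_law(series: LatticeTimeSeries, field: str,
                   through_origin: bool = False) -> SlopeFit:
    """Fit the linear law for (field_t/field_0 - 1)**2 with the sign restored
    from the direction of the raw period change over the series."""
    t, y = squared_rel_variation(series, field)
    v = series.column(field)
    sign = -1 if v[-1] < v[0] else 1
    return fit_linear(t, y, sign=sign, through_origin=through_origin)


def slope_ratio(fit_a: SlopeFit, fit_b: SlopeFit) -> tuple[float, int]:
    """Time scale factor |slope_a| / |slope_b| and its nearest integer."""
    if fit_b.magnitude == 0:
        raise ZeroDivisionError("denominator slope is zero")
    f = fit_a.magnitude / fit_b.magnitude
    return f, round(f)


def delta_rho_trend(series: LatticeTimeSeries) -> SlopeFit:
    """OLS trend of the overlap/gap contrast delta_rho versus time (day^-1)."""
    return fit_linear(series.t, series.column("delta_rho"))


def delta_rho_increment(series: LatticeTimeSeries) -> float:
    """Endpoint contrast increment delta_rho(final) - delta_rho(0)."""
    rho = series.column("delta_rho")
    return float(rho[-1] - rho[0])


def volume_change(fit_d_E: SlopeFit, fit_d_M: SlopeFit,
                  r_E: float | None = None, r_M: float | None = None) -> dict[str, float]:
    """Fibril volume change rate from the two signed period slopes.

    Primary value: ``(slope_dE + 1) * (slope_dM + 1) - 1`` on the signed
    slopes (first-order combination of the two drift rates).  If period
    ratios at a chosen time are supplied, the geometric alternative
    ``(1 + r_E)**2 * (1 + r_M) - 1`` is also reported.
    """
    dv = (fit_d_E.slope + 1.0) * (fit_d_M.slope + 1.0) - 1.0
    out = {"delta_V": float(dv)}
    if r_E is not None and r_M is not None:
        out["delta_V_geometric"] = float((1.0 + r_E) ** 2 * (1.0 + r_M) - 1.0)
    return out
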