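"""Time-series analytics for impedance-based growth monitoring.

Given an hourly series of fitted spectra and a sparser mass series, these
routines extract the impedance modulus at target frequencies (10 Hz and
0.1 MHz by default), estimate linear and exponential rates over configurable
windows, min-max normalize trajectories, correlate normalized mass with
normalized impedance (Pearson), regress impedance on the fitted double-layer
capacitance, and check medium-only controls for drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .series import MonitoringSeries

__all__ = [
    "RateEstimate",
    "CorrelationResult",
    "RegressionResult",
    "DriftSummary",
    "DEFAULT_WINDOWS",
    "impedance_at",
    "estimate_rate",
    "minmax_normalize",
    "mass_impedance_correlation",
    "relative_change",
    "impedance_cdl_regression",
    "control_drift_check",
]

#: Default analysis windows in hours: impedance rates over 24-144 h, mass
#: rates over the first 96 h, Rct exponential growth from its onset (72 h in
#: auxin-rich cultures, 96 h in auxin-free) to 24 h before the series end.
DEFAULT_WINDOWS = {
    "impedance": (24.0, 144.0),
    "mass": (0.0, 96.0),
    "rct_auxin_rich": (72.0, 144.0),
    "rct_auxin_free": (96.0, 168.0),
}


@dataclass(frozen=True)
class RateEstimate:
    """A fitted growth rate over a time window.

    ``rate`` is always the window-mean slope in base units per hour (the
    convention in which Rct rates are quoted, Ω·cm²/h); for the exponential
    model ``rate_constant`` additionally carries the exponent in h⁻¹.
    """

    rate: float
    intercept: float
    r_squared: float
    window: tuple[float, float]
    model: str  # "linear" | "exponential"
    rate_constant: Optional[float] = None
    stderr: Optional[float] = None
    n_points: int = 0

    @property
    def rate_per_day(self) -> float:
        return self.rate * 24.0


class CorrelationResult(NamedTuple):
    pearson_r: float
    n_points: int
    normalized_x: np.ndarray
    normalized_y: np.ndarray
    p_value: float


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class DriftSummary:
    """Stability assessment of a medium-only control trajectory."""

    max_abs_deviation: float
    drift_rate_per_hour: float
    initial_value: float
    relative_max_deviation: float
    threshold: float
    passed: bool


def impedance_at(series: MonitoringSeries, target_freq: float) -> pd.Series:
    """Impedance modulus |Z| at `target_freq` (Hz) for every timepoint.

    The grid point nearest in log-frequency is used; when it is more than 2%
    away in frequency the modulus is log-log interpolated between the
    bracketing points.  Returns a Series indexed by time in hours.
    """
    values = np.empty(len(series))
    for i, (t, spec) in enumerate(zip(series.timepoints, series.spectra)):
        f = spec.frequencies
        if not (f[0] <= target_freq <= f[-1]):
            raise ValueError(
                f"target frequency {target_freq} Hz outside measured range "
                f"[{f[0]}, {f[-1]}] Hz at timepoint {t} h")
        logt = np.log10(target_freq)
        idx = int(np.argmin(np.abs(np.log10(f) - logt)))
        if abs(f[idx] - target_freq) <= 0.02 * target_freq:
            values[i] = spec.modulus[idx]
        else:
            values[i] = 10 ** np.interp(logt, np.log10(f),
                                        np.log10(spec.modulus))
    return pd.Series(values, index=pd.Index(series.timepoints, name="time_h"),
                     name=f"z_mod_{target_freq:g}hz")


def estimate_rate(values: pd.Series,
                  window: tuple[float, float] | None = None,
                  model: str = "linear") -> RateEstimate:
    """Estimate a growth rate from a time-indexed series.

    linear
        Ordinary least squares on the windowed points; ``rate`` is the slope
        in base units per hour.
    exponential
        Least squares on log-transformed values (requires all positive);
        ``rate_constant`` is the exponent in h⁻¹ and ``rate`` the window-mean
        slope ``(y(t1) - y(t0)) / (t1 - t0)`` of the fitted exponential.
    """
    t = np.asarray(values.index, dtype=float)
    y = np.asarray(values.values, dtype=float)
    if window is None:
        window = (float(t.min()), float(t.max()))
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"window must be increasing, got {window}")
    sel = (t >= t0) & (t <= t1) & np.isfinite(y)
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 points inside window {window}, "
                         f"have {int(sel.sum())}")
    tw, yw = t[sel], y[sel]

    if model == "linear":
        res = stats.linregress(tw, yw)
        return RateEstimate(rate=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            window=(t0, t1), model="linear",
                            stderr=float(res.stderr),
                            n_points=int(sel.sum()))
    if model == "exponential":
        if np.any(yw <= 0):
            raise ValueError("exponential model requires positive values")
        res = stats.linregress(tw, np.log(yw))
        k = float(res.slope)
        amp = float(np.exp(res.intercept))
        y0, y1 = amp * np.exp(k * t0), amp * np.exp(k * t1)
        return RateEstimate(rate=(y1 - y0) / (t1 - t0),
                            intercept=amp,
                            r_squared=float(res.rvalue ** 2),
                            window=(t0, t1), model="exponential",
                            rate_constant=k,
                            stderr=float(res.stderr),
                            n_points=int(sel.sum()))
    raise ValueError(f"model must be 'linear' or 'exponential', got {model!r}")


def minmax_normalize(values) -> pd.Series | np.ndarray:
    """Min-max normalization, ``(X - Xmin) / (Xmax - Xmin)``, onto [0, 1]."""
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        raise ValueError("constant series: min-max normalization undefined")
    out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def mass_impedance_correlation(series: MonitoringSeries,
                               freq: float = 10.0) -> CorrelationResult:
    """Pearson correlation between normalized mass and normalized |Z|@freq.

    Mass timepoints (typically 24-hourly) are matched to the nearest hourly
    impedance timepoint; both series are min-max normalized before the
    correlation, which leaves Pearson's r unchanged (affine invariance) but
    mirrors how the trajectories are compared visually.
    """
    if series.masses is None:
        raise ValueError("series has no mass measurements")
    z = impedance_at(series, freq)
    mass = series.masses.dropna(subset=["time_h", "mass_mg"])
    z_times = np.asarray(z.index, dtype=float)
    matched_z, matched_m = [], []
    for _, row in mass.iterrows():
        j = int(np.argmin(np.abs(z_times - row["time_h"])))
        if abs(z_times[j] - row["time_h"]) <= 0.5 + 1e-9:  # nearest hour
            matched_z.append(z.iloc[j])
            matched_m.append(row["mass_mg"])
        else:
            # mass point has no impedance neighbour within the hourly grid
            continue
    if len(matched_z) < 3:
        raise ValueError(
            f"need >= 3 aligned mass/impedance timepoints, have {len(matched_z)}")
    zn = minmax_normalize(np.asarray(matched_z))
    mn = minmax_normalize(np.asarray(matched_m))
    r, p = stats.pearsonr(mn, zn)
    return CorrelationResult(pearson_r=float(r), n_points=len(matched_z),
                             normalized_x=mn, normalized_y=zn,
                             p_value=float(p))


def relative_change(initial: float, final: float) -> float:
    """Percent change relative to the initial value, ``100 (x0 - x1) / x0``.

    Positive for declines (the convention in which capacitance losses and
    rate reductions are quoted); also serves for rate comparisons
    ``100 (r_a - r_b) / r_a``.
    """
    if initial == 0:
        raise ValueError("relative change undefined for zero initial value")
    return 100.0 * (initial - final) / initial


def impedance_cdl_regression(series: MonitoringSeries,
                             freq: float = 10.0,
                             window: tuple[float, float] | None = None
                             ) -> RegressionResult:
    """OLS of |Z|@freq against the fitted double-layer capacitance.

    A tight linear relation (R² near 1) indicates that the low-frequency
    impedance trend is driven by the capacitance decline.  Returns slope in
    Ω/F, intercept in Ω, and R².  Requires fits on the series.
    """
    if series.fits is None:
        raise ValueError("series has no fits; run fit_series first")
    z = impedance_at(series, freq)
    table = series.fit_table()
    t = table["time_h"].to_numpy()
    cdl = table["cdl_f"].to_numpy()
    if window is None:
        window = (float(t.min()), float(t.max()))
    sel = ((t >= window[0]) & (t <= window[1])
           & np.isfinite(cdl) & table["converged"].to_numpy(bool))
    if sel.sum() < 3:
        raise ValueError(f"need >= 3 fitted timepoints in window {window}; "
                         "run fit_series over the window first")
    x, y = cdl[sel], z.to_numpy()[sel]
    if np.ptp(x) == 0:
        return RegressionResult(slope=np.nan, intercept=float(np.mean(y)),
                                r_squared=0.0)
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2))


def control_drift_check(control: MonitoringSeries,
                        freq: float = 10.0,
                        threshold: float = 0.05) -> DriftSummary:
    """Stability check of a medium-only control at the target frequency.

    Reports the maximum absolute deviation of |Z|@freq from its initial
    value and the linear drift rate; the control passes when the maximum
    relative deviation stays below `threshold` (default 5% of the initial
    value).
    """
    z = impedance_at(control, freq)
    z0 = float(z.iloc[0])
    dev = np.abs(z.to_numpy() - z0)
    max_dev = float(dev.max())
    rel = max_dev / abs(z0) if z0 != 0 else np.inf
    drift = estimate_rate(z, model="linear")
    return DriftSummary(max_abs_deviation=max_dev,
                        drift_rate_per_hour=drift.rate,
                        initial_value=z0,
                        relative_max_deviation=rel,
                        threshold=threshold,
                        passed=rel <= threshold)
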