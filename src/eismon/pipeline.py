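"""End-to-end monitoring pipeline and report generation.

``run_monitor`` chains the stages: load a series directory, fit every
spectrum, extract |Z| at the low and high target frequencies, estimate rates
over the configured windows, correlate normalized mass with normalized
impedance, regress impedance on the fitted double-layer capacitance,
summarize relative changes, and check the medium-only control for drift.
The report is a versioned JSON document in which every quantity carries its
units and the analysis window it came from; numbers are never rounded (the
human-readable summary rounds, the JSON does not) and wall-clock timestamps
live in a separate field so identical runs produce identical payloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .circuit import DEFAULT_ELECTRODE_AREA_CM2
from .fitting import fit_series
from .monitoring import (
    DEFAULT_WINDOWS,
    control_drift_check,
    estimate_rate,
    impedance_at,
    impedance_cdl_regression,
    mass_impedance_correlation,
    relative_change,
)
from .series import MonitoringSeries

__all__ = ["PipelineConfig", "run_monitor", "report_summary",
           "REPORT_SCHEMA_VERSION"]

log = logging.getLogger("eismon")

REPORT_SCHEMA_VERSION = "1.0"


@dataclasses.dataclass
class PipelineConfig:
    """Knobs of the monitoring pipeline with the study's defaults."""

    electrode_area: float = DEFAULT_ELECTRODE_AREA_CM2  # cm2
    low_freq: float = 10.0       # Hz
    high_freq: float = 1e5       # Hz (0.1 MHz)
    weighting: str = "modulus"
    ftol: float = 1e-10
    max_iter: int = 500
    impedance_window: tuple[float, float] = DEFAULT_WINDOWS["impedance"]
    mass_window: tuple[float, float] = DEFAULT_WINDOWS["mass"]
    rct_window_auxin_rich: tuple[float, float] = DEFAULT_WINDOWS["rct_auxin_rich"]
    rct_window_auxin_free: tuple[float, float] = DEFAULT_WINDOWS["rct_auxin_free"]
    stability_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.electrode_area <= 0:
            raise ValueError("electrode_area must be positive")
        for name in ("impedance_window", "mass_window",
                     "rct_window_auxin_rich", "rct_window_auxin_free"):
            w = tuple(getattr(self, name))
            if w[1] <= w[0]:
                raise ValueError(f"{name} must be increasing, got {w}")
            setattr(self, name, w)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def rct_window_for(self, condition: Optional[str]) -> tuple[float, float]:
        if condition and "free" in condition:
            return self.rct_window_auxin_free
        return self.rct_window_auxin_rich


def _rate_dict(est) -> dict:
    d = {"rate_per_hour": est.rate, "rate_per_day": est.rate_per_day,
         "intercept": est.intercept, "r_squared": est.r_squared,
         "window_h": list(est.window), "model": est.model,
         "n_points": est.n_points}
    if est.rate_constant is not None:
        d["rate_constant_per_hour"] = est.rate_constant
    return d


def run_monitor(series: MonitoringSeries | str | Path,
                control: MonitoringSeries | str | Path | None = None,
                config: Optional[PipelineConfig] = None,
                out_dir: str | Path | None = None) -> dict:
    """Run the full analysis on a series (object or directory path).

    Returns the report dict; when `out_dir` is given also writes
    ``report.json``, the fitted-parameter table ``fits.csv`` and the
    extracted impedance trajectories ``impedance.csv``.
    """
    cfg = config or PipelineConfig()
    if not isinstance(series, MonitoringSeries):
        series = MonitoringSeries.read_dir(series)
    if control is not None and not isinstance(control, MonitoringSeries):
        control = MonitoringSeries.read_dir(control)

    log.info("fitting %d spectra (%s weighting)", len(series), cfg.weighting)
    if series.fits is None:
        fit_series(series, weighting=cfg.weighting, area=cfg.electrode_area,
                   ftol=cfg.ftol, max_iter=cfg.max_iter)
    table = series.fit_table()
    n_conv = int(table["converged"].sum())
    log.info("converged %d/%d fits", n_conv, len(series))
    if len(series) - n_conv > 0.05 * len(series):
        log.warning("more than 5%% of fits failed to converge (%d/%d)",
                    len(series) - n_conv, len(series))

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "condition": series.condition,
        "config": {
            "electrode_area_cm2": cfg.electrode_area,
            "low_freq_hz": cfg.low_freq,
            "high_freq_hz": cfg.high_freq,
            "weighting": cfg.weighting,
            "stability_threshold": cfg.stability_threshold,
            "seed": cfg.seed,
        },
        "fits": {"n_timepoints": len(series), "n_converged": n_conv},
    }

    # impedance trajectories and rates
    z_low = impedance_at(series, cfg.low_freq)
    z_high = impedance_at(series, cfg.high_freq)
    z_rate_low = estimate_rate(z_low, cfg.impedance_window, model="linear")
    z_rate_high = estimate_rate(z_high, cfg.impedance_window, model="linear")
    report["impedance"] = {
        "units": "ohm",
        "low_freq_rate": _rate_dict(z_rate_low),
        "high_freq_rate": _rate_dict(z_rate_high),
    }

    # mass rate
    if series.masses is not None:
        mass_series = pd.Series(series.masses["mass_mg"].to_numpy(),
                                index=series.masses["time_h"].to_numpy())
        m_rate = estimate_rate(mass_series, cfg.mass_window, model="linear")
        report["mass"] = {"units": "mg",
                          "rate": _rate_dict(m_rate),
                          "rate_ug_per_hour": m_rate.rate * 1e3}
        corr = mass_impedance_correlation(series, cfg.low_freq)
        report["correlation"] = {
            "pearson_r": corr.pearson_r,
            "p_value": corr.p_value,
            "n_points": corr.n_points,
            "freq_hz": cfg.low_freq,
            "normalization": "min-max",
        }
    else:
        log.warning("no mass.csv found; skipping mass rate and correlation")

    # Rct trajectory (area-normalized) and exponential growth rate
    conv = table[table["converged"]]
    rct_series = pd.Series(conv["rct_ohm_cm2"].to_numpy(),
                           index=conv["time_h"].to_numpy())
    rct_window = cfg.rct_window_for(series.condition)
    rct_entry: dict = {"units": "ohm_cm2"}
    try:
        r_rct = estimate_rate(rct_series, rct_window, model="exponential")
        rct_entry["exponential"] = _rate_dict(r_rct)
        rct_entry["r_rct_ohm_cm2_per_hour"] = r_rct.rate
    except ValueError as exc:
        rct_entry["error"] = str(exc)
    report["rct"] = rct_entry

    # Cdl endpoints and relative change
    cdl = conv["cdl_uf_per_cm2"].to_numpy()
    if cdl.size >= 2:
        report["cdl"] = {
            "units": "uF_per_cm2",
            "start": float(cdl[0]),
            "end": float(cdl[-1]),
            "relative_decline_pct": relative_change(float(cdl[0]),
                                                    float(cdl[-1])),
        }
        reg = impedance_cdl_regression(series, cfg.low_freq)
        report["impedance_vs_cdl"] = {
            "slope_ohm_per_f": reg.slope,
            "intercept_ohm": reg.intercept,
            "r_squared": reg.r_squared,
            "freq_hz": cfg.low_freq,
        }

    if control is not None:
        drift = control_drift_check(control, cfg.low_freq,
                                    cfg.stability_threshold)
        report["control"] = {
            "max_abs_deviation_ohm": drift.max_abs_deviation,
            "relative_max_deviation": drift.relative_max_deviation,
            "drift_rate_ohm_per_hour": drift.drift_rate_per_hour,
            "threshold": drift.threshold,
            "stable": drift.passed,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = dict(report)
        payload["generated_at"] = datetime.now(timezone.utc).isoformat()
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
        table.to_csv(out_dir / "fits.csv", index=False)
        traj = pd.DataFrame({"time_h": z_low.index,
                             f"z_mod_{cfg.low_freq:g}hz_ohm": z_low.values,
                             f"z_mod_{cfg.high_freq:g}hz_ohm": z_high.values})
        traj.to_csv(out_dir / "impedance.csv", index=False)
        log.info("wrote report to %s", out_dir / "report.json")

    return report


def report_summary(report: dict) -> str:
    """Human-readable, rounded rendering of a report dict."""
    lines = [f"condition: {report.get('condition')}",
             f"fits: {report['fits']['n_converged']}/"
             f"{report['fits']['n_timepoints']} converged"]
    z = report.get("impedance", {})
    if z:
        lo = z["low_freq_rate"]
        lines.append(
            f"|Z| rate @ low freq: {lo['rate_per_hour']:.3g} ohm/h "
            f"({lo['rate_per_day']:.3g} ohm/day), R2={lo['r_squared']:.3f}, "
            f"window {lo['window_h']} h")
    if "mass" in report:
        m = report["mass"]["rate"]
        lines.append(f"mass rate: {report['mass']['rate_ug_per_hour']:.3g} ug/h, "
                     f"R2={m['r_squared']:.3f}, window {m['window_h']} h")
    if "correlation" in report:
        c = report["correlation"]
        lines.append(f"mass-impedance Pearson r: {c['pearson_r']:.3f} "
                     f"(n={c['n_points']}, p={c['p_value']:.2g})")
    if "rct" in report and "r_rct_ohm_cm2_per_hour" in report["rct"]:
        r = report["rct"]
        lines.append(f"r_Rct: {r['r_rct_ohm_cm2_per_hour']:.3g} ohm cm2/h "
                     f"(window {r['exponential']['window_h']} h)")
    if "cdl" in report:
        c = report["cdl"]
        lines.append(f"Cdl: {c['start']:.4g} -> {c['end']:.4g} uF/cm2 "
                     f"({c['relative_decline_pct']:.1f}% decline)")
    if "impedance_vs_cdl" in report:
        g = report["impedance_vs_cdl"]
        lines.append(f"|Z| vs Cdl regression: R2={g['r_squared']:.3f}")
    if "control" in report:
        c = report["control"]
        status = "stable" if c["stable"] else "DRIFTING"
        lines.append(f"control: {status} (max relative deviation "
                     f"{100 * c['relative_max_deviation']:.2f}%, threshold "
                     f"{100 * c['threshold']:.0f}%)")
    return "\n".join(lines)
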