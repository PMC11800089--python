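"""Time-indexed collections of impedance spectra with optional mass data.

A :class:`MonitoringSeries` holds one recording campaign: hourly spectra over
(typically) 168 h, an optional sparser mass series, per-timepoint circuit
fits once computed, and an optional medium-only control companion.  Series
round-trip through a plain-text directory layout::

    series_dir/
      manifest.csv        # time_h,spectrum_file,label
      spectrum_0000.csv   # frequency_hz,z_real_ohm,z_imag_ohm
      ...
      mass.csv            # time_h,mass_mg (optional)
      scenario.json       # generator provenance (optional)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .circuit import Spectrum

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import FitResult

__all__ = ["MonitoringSeries"]


@dataclass
class MonitoringSeries:
    """Spectra (and optionally masses and fits) indexed by time in hours."""

    timepoints: np.ndarray
    spectra: list[Spectrum]
    masses: Optional[pd.DataFrame] = None  # columns: time_h, mass_mg
    fits: Optional[list["FitResult"]] = None
    condition: Optional[str] = None
    control: Optional["MonitoringSeries"] = None

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.timepoints.ndim != 1 or self.timepoints.size == 0:
            raise ValueError("timepoints must be a non-empty 1-D array")
        if self.timepoints.size > 1 and not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.spectra) != self.timepoints.size:
            raise ValueError(
                f"{len(self.spectra)} spectra for {self.timepoints.size} timepoints"
            )
        if self.masses is not None:
            missing = {"time_h", "mass_mg"} - set(self.masses.columns)
            if missing:
                raise ValueError(f"mass table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return self.timepoints.size

    # ------------------------------------------------------------------
    def fit_table(self) -> pd.DataFrame:
        """Tidy per-timepoint table of fitted circuit parameters.

        Columns: ``time_h, rsol_ohm, rct_ohm, q_s_sn, n, cdl_f,
        cdl_uf_per_cm2, rct_ohm_cm2, chi_sq, converged``.  Requires
        :func:`eismon.fitting.fit_series` to have been run.
        """
        if self.fits is None:
            raise ValueError("no fits present; run fit_series first")
        rows = []
        for t, fr in zip(self.timepoints, self.fits):
            if fr.params is None:
                rows.append({"time_h": t, "rsol_ohm": np.nan, "rct_ohm": np.nan,
                             "q_s_sn": np.nan, "n": np.nan, "cdl_f": np.nan,
                             "cdl_uf_per_cm2": np.nan, "rct_ohm_cm2": np.nan,
                             "chi_sq": np.nan, "converged": False})
            else:
                p = fr.params
                rows.append({"time_h": t, "rsol_ohm": p.rsol, "rct_ohm": p.rct,
                             "q_s_sn": p.q, "n": p.n, "cdl_f": fr.cdl,
                             "cdl_uf_per_cm2": p.cdl_uf_per_cm2,
                             "rct_ohm_cm2": p.rct_ohm_cm2,
                             "chi_sq": fr.chi_sq, "converged": fr.converged})
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------
    def write_dir(self, path: str | Path,
                  scenario: Optional[dict] = None) -> Path:
        """Materialize the series as a plain-text directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, (t, spec) in enumerate(zip(self.timepoints, self.spectra)):
            fname = f"spectrum_{i:04d}.csv"
            spec.to_csv(path / fname)
            rows.append({"time_h": t, "spectrum_file": fname,
                         "label": spec.label or self.condition or ""})
        pd.DataFrame(rows).to_csv(path / "manifest.csv", index=False)
        if self.masses is not None:
            self.masses.to_csv(path / "mass.csv", index=False)
        if scenario is not None:
            (path / "scenario.json").write_text(json.dumps(scenario, indent=2))
        return path

    @classmethod
    def read_dir(cls, path: str | Path) -> "MonitoringSeries":
        """Load a series directory written by :meth:`write_dir`."""
        path = Path(path)
        manifest_path = path / "manifest.csv"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest.csv in {path}")
        manifest = pd.read_csv(manifest_path).sort_values("time_h")
        spectra = []
        for _, row in manifest.iterrows():
            spec = Spectrum.from_csv(path / row["spectrum_file"])
            if spec.timestamp is None:
                spec.timestamp = float(row["time_h"])
            spectra.append(spec)
        masses = None
        if (path / "mass.csv").exists():
            masses = pd.read_csv(path / "mass.csv")
        condition = None
        labels = manifest["label"].dropna().unique() if "label" in manifest else []
        if len(labels) == 1 and str(labels[0]):
            condition = str(labels[0])
        return cls(manifest["time_h"].to_numpy(float), spectra,
                   masses=masses, condition=condition)
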