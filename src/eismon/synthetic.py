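"""Synthetic impedance/mass series emulating 7-day callus monitoring runs.

Real recordings of this kind are hourly EIS sweeps (1 Hz - 1 MHz) over 168 h
plus 24-hourly mass measurements.  No public recordings exist, so the
generator produces series with the reported statistical structure instead:

* the double-layer capacitance declines linearly between its reported
  start/end values (13.32 -> 9.93 uF/cm2 in auxin-rich medium,
  10.15 -> 8.73 uF/cm2 in auxin-free medium);
* the charge-transfer resistance dips mildly until 48 h, stays flat until a
  growth onset (72 h auxin-rich, 96 h auxin-free), then grows exponentially
  with a rate constant calibrated so the window-mean slope matches the
  reported r_Rct (3 and 1.8 Ohm cm2/h);
* the solution resistance drifts linearly (28 and 36.2 Ohm/day);
* mass grows linearly at the reported r_m (12.8 and 8.1 ug/h) from ~20 mg.

Proportional complex Gaussian noise is added to the spectra and additive
Gaussian noise to the masses.  One root seed deterministically derives an
independent stream per timepoint, so extending a series never reshuffles
earlier points.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .circuit import (
    DEFAULT_ELECTRODE_AREA_CM2,
    CircuitParams,
    Spectrum,
    circuit_impedance,
    log_frequency_grid,
    q_from_cdl,
)
from .series import MonitoringSeries

__all__ = ["GrowthScenario", "scenario_preset", "params_at",
           "simulate_series", "PRESET_NAMES"]

PRESET_NAMES = ("auxin_rich", "auxin_free", "medium_only")


@dataclass(frozen=True)
class GrowthScenario:
    """Parameter trajectories and noise specification for one condition.

    Capacitance and charge-transfer values are area-normalized (uF/cm2 and
    Ohm cm2, the units growth results are quoted in); the generator converts
    to raw F and Ohm with the electrode area before evaluating the circuit.
    """

    name: str = "custom"
    duration: float = 168.0            # h
    spectrum_interval: float = 1.0     # h
    mass_interval: float = 24.0        # h
    cdl_start: float = 13.32           # uF/cm2
    cdl_end: float = 9.93              # uF/cm2
    n_cpe: float = 0.9                 # CPE exponent, constant over time
    rct_baseline: float = 1e4          # Ohm cm2
    rct_dip_until: float = 48.0        # h
    rct_dip_depth: float = 0.10        # fractional dip before the plateau
    rct_stable_until: float = 72.0     # h, growth onset
    rct_growth_until: float = 144.0    # h, end of the exponential window
    rct_rate: float = 3.0              # Ohm cm2 / h, window-mean slope
    rsol_start: float = 100.0          # Ohm
    rsol_drift: float = 28.0           # Ohm / day
    mass_start: float = 20.0           # mg
    mass_rate: float = 12.8            # ug / h
    include_mass: bool = True
    noise_alpha: float = 0.01          # proportional spectrum noise fraction
    mass_sigma: float = 0.2            # mg
    area: float = DEFAULT_ELECTRODE_AREA_CM2  # cm2
    f_min: float = 1.0                 # Hz
    f_max: float = 1e6                 # Hz
    points_per_decade: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.spectrum_interval <= 0:
            raise ValueError("duration and spectrum_interval must be positive")
        if not (self.cdl_start > 0 and self.cdl_end > 0):
            raise ValueError("Cdl endpoints must be positive")
        if not 0 < self.n_cpe <= 1:
            raise ValueError("n_cpe must lie in (0, 1]")
        if not (0 <= self.rct_dip_until <= self.rct_stable_until
                <= self.duration):
            raise ValueError(
                "need 0 <= rct_dip_until <= rct_stable_until <= duration")
        if not 0 <= self.rct_dip_depth < 1:
            raise ValueError("rct_dip_depth must lie in [0, 1)")
        if self.rct_growth_until <= self.rct_stable_until:
            raise ValueError("rct_growth_until must exceed rct_stable_until")

    def replace(self, **changes) -> "GrowthScenario":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return asdict(self)

    @property
    def rct_rate_constant(self) -> float:
        """Exponential rate constant (1/h) giving the target window-mean slope.

        With plateau value R0 and growth window length W, the constant k
        solves (R0 e^{kW} - R0) / W = rct_rate.
        """
        if self.rct_rate == 0:
            return 0.0
        r0 = (1.0 - self.rct_dip_depth) * self.rct_baseline
        w = self.rct_growth_until - self.rct_stable_until
        return math.log1p(self.rct_rate * w / r0) / w


_PRESETS = {
    "auxin_rich": dict(cdl_start=13.32, cdl_end=9.93, rct_stable_until=72.0,
                       rct_growth_until=144.0, rct_rate=3.0,
                       rsol_drift=28.0, mass_rate=12.8),
    "auxin_free": dict(cdl_start=10.15, cdl_end=8.73, rct_stable_until=96.0,
                       rct_growth_until=168.0, rct_rate=1.8,
                       rsol_drift=36.2, mass_rate=8.1),
    "medium_only": dict(cdl_start=10.0, cdl_end=10.0, rct_dip_depth=0.0,
                        rct_rate=0.0, rsol_drift=0.0, mass_rate=0.0,
                        include_mass=False),
}


def scenario_preset(name: str, rct_rate_convention: str = "results",
                    **overrides) -> GrowthScenario:
    """Named study conditions: ``auxin_rich``, ``auxin_free``, ``medium_only``.

    The Rct growth rate has been quoted both as Ohm cm2/h and kOhm cm2/h for
    the same conditions; ``rct_rate_convention`` selects the reading
    ("results" -> 3 / 1.8 Ohm cm2/h, "discussion" -> 1000x that).  Keyword
    overrides replace any scenario field.
    """
    if name not in _PRESETS:
        raise ValueError(
            f"unknown scenario {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    fields = dict(_PRESETS[name])
    if rct_rate_convention == "discussion":
        fields["rct_rate"] = fields["rct_rate"] * 1000.0
    elif rct_rate_convention != "results":
        raise ValueError("rct_rate_convention must be 'results' or 'discussion'")
    fields.update(overrides)
    return GrowthScenario(name=name, **fields)


def params_at(scenario: GrowthScenario, t: float) -> CircuitParams:
    """Ground-truth circuit parameters at time `t` hours (raw Ohm and F).

    The Rct trajectory is continuous at both breakpoints: a linear dip to
    ``(1 - dip_depth) * baseline`` at ``rct_dip_until``, a plateau to the
    growth onset, then exponential growth at the calibrated rate constant.
    """
    if not 0 <= t <= scenario.duration:
        raise ValueError(f"t={t} outside [0, {scenario.duration}] h")
    s = scenario

    frac = t / s.duration
    cdl_uf_cm2 = s.cdl_start + (s.cdl_end - s.cdl_start) * frac
    cdl_raw = cdl_uf_cm2 * 1e-6 * s.area  # uF/cm2 -> F

    r0 = (1.0 - s.rct_dip_depth) * s.rct_baseline
    if t <= s.rct_dip_until:
        if s.rct_dip_until > 0:
            rct_cm2 = s.rct_baseline + (r0 - s.rct_baseline) * t / s.rct_dip_until
        else:
            rct_cm2 = r0
    elif t <= s.rct_stable_until:
        rct_cm2 = r0
    else:
        rct_cm2 = r0 * math.exp(s.rct_rate_constant * (t - s.rct_stable_until))
    rct_raw = rct_cm2 / s.area  # Ohm cm2 -> Ohm

    rsol = s.rsol_start + s.rsol_drift * t / 24.0
    q = q_from_cdl(cdl_raw, s.n_cpe, rct_raw)
    return CircuitParams(rsol=rsol, rct=rct_raw, q=q, n=s.n_cpe, area=s.area)


def _timepoint_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # independent stream per (kind, timepoint); extending the series keeps
    # earlier draws bit-identical
    return np.random.default_rng(np.random.SeedSequence((seed, stream, index)))


def simulate_series(scenario: GrowthScenario,
                    seed: Optional[int] = None) -> MonitoringSeries:
    """Generate a full monitoring series (spectra + masses) for a scenario.

    Spectra are the circuit forward model on a log grid with independent
    Gaussian noise of standard deviation ``noise_alpha * |Z|`` on the real
    and imaginary parts; masses are ``mass_start + mass_rate * t`` plus
    Gaussian noise.  Identical seeds give bit-identical series.
    """
    s = scenario if seed is None else scenario.replace(seed=seed)
    freqs = log_frequency_grid(s.f_min, s.f_max, s.points_per_decade)
    n_spec = int(round(s.duration / s.spectrum_interval)) + 1
    times = np.arange(n_spec) * s.spectrum_interval

    spectra = []
    for i, t in enumerate(times):
        z = circuit_impedance(freqs, params_at(s, float(t)))
        if s.noise_alpha > 0:
            rng = _timepoint_rng(s.seed, 0, i)
            sigma = s.noise_alpha * np.abs(z)
            z = z + rng.normal(0, sigma) + 1j * rng.normal(0, sigma)
        spectra.append(Spectrum(freqs, z, timestamp=float(t), label=s.name))

    masses = None
    if s.include_mass:
        n_mass = int(round(s.duration / s.mass_interval)) + 1
        mass_times = np.arange(n_mass) * s.mass_interval
        mass = s.mass_start + s.mass_rate * 1e-3 * mass_times  # ug/h -> mg/h
        if s.mass_sigma > 0:
            noise = np.array([
                _timepoint_rng(s.seed, 1, j).normal(0, s.mass_sigma)
                for j in range(n_mass)])
            mass = mass + noise
        masses = pd.DataFrame({"time_h": mass_times, "mass_mg": mass})

    return MonitoringSeries(times, spectra, masses=masses, condition=s.name)
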