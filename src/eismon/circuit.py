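"""Equivalent-circuit forward model for two-electrode impedance spectra.

The cell is modelled as a spreading (solution) resistance ``Rsol`` in series
with the interfacial branch: a constant phase element (CPE) in parallel with
a charge transfer resistance ``Rct``.  The CPE impedance is

    Z_CPE(omega) = 1 / (Q * (j*omega)**n),      0 < n <= 1,

so the full circuit reads

    Z(omega) = Rsol + Rct / (1 + Q * (j*omega)**n * Rct).

At ``n = 1`` the CPE is an ideal capacitor and the circuit reduces to the
textbook Randles RC form.  The effective double-layer capacitance is
recovered from the CPE parameters as ``Cdl = (Q * Rct)**(1/n) / Rct``.

All public functions take linear frequency in Hz at the file/series level and
convert internally with ``omega = 2*pi*f``; capacitive reactance is negative
imaginary (``Z = Z' + jZ''`` with ``Z'' <= 0``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CircuitParams",
    "Spectrum",
    "cpe_impedance",
    "circuit_impedance",
    "cdl_from_cpe",
    "area_normalize",
    "area_denormalize",
    "parallel_capacitance",
    "modulus_phase",
    "DEFAULT_ELECTRODE_AREA_CM2",
]

#: Geometric area of one circular gold electrode (6 mm^2), in cm^2.
DEFAULT_ELECTRODE_AREA_CM2 = 0.06


def _check_cpe(q: float, n: float) -> None:
    if not q > 0:
        raise ValueError(f"CPE magnitude Q must be positive, got {q!r}")
    if not 0 < n <= 1:
        raise ValueError(f"CPE exponent n must lie in (0, 1], got {n!r}")


@dataclass(frozen=True)
class CircuitParams:
    """State of the Rsol + (CPE || Rct) equivalent circuit.

    Parameters
    ----------
    rsol : float
        Spreading / solution resistance, Ω.  Non-negative.
    rct : float
        Charge transfer resistance, Ω.  Strictly positive.
    q : float
        CPE magnitude, S·sⁿ.  Strictly positive.
    n : float
        Dimensionless CPE exponent in (0, 1]; ``n = 1`` is an ideal capacitor.
    area : float
        Electrode area in cm², metadata used only when reporting
        area-normalized quantities (Ω·cm², F·cm⁻²).
    """

    rsol: float
    rct: float
    q: float
    n: float
    area: float = DEFAULT_ELECTRODE_AREA_CM2

    def __post_init__(self) -> None:
        if not self.rsol >= 0:
            raise ValueError(f"Rsol must be non-negative, got {self.rsol!r}")
        if not self.rct > 0:
            raise ValueError(f"Rct must be positive, got {self.rct!r}")
        _check_cpe(self.q, self.n)
        if not self.area > 0:
            raise ValueError(f"area must be positive, got {self.area!r}")

    @property
    def cdl(self) -> float:
        """Double-layer capacitance in F derived from the CPE parameters."""
        return cdl_from_cpe(self.q, self.n, self.rct)

    @property
    def cdl_uf_per_cm2(self) -> float:
        """Area-normalized double-layer capacitance, μF·cm⁻²."""
        return area_normalize(self.cdl, self.area, "capacitance") * 1e6

    @property
    def rct_ohm_cm2(self) -> float:
        """Area-normalized charge transfer resistance, Ω·cm²."""
        return area_normalize(self.rct, self.area, "resistance")

    def replace(self, **changes) -> "CircuitParams":
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {"rsol": self.rsol, "rct": self.rct, "q": self.q,
                "n": self.n, "area": self.area}


@dataclass
class Spectrum:
    """One impedance sweep: complex impedance on an ascending frequency grid."""

    frequencies: np.ndarray
    impedance: np.ndarray
    timestamp: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.frequencies.ndim != 1 or self.impedance.ndim != 1:
            raise ValueError("frequencies and impedance must be 1-D arrays")
        if self.frequencies.size != self.impedance.size:
            raise ValueError("frequencies and impedance must have equal length")
        if self.frequencies.size < 2:
            raise ValueError("a spectrum needs at least 2 frequency points")
        if not np.all(self.frequencies > 0):
            raise ValueError("all frequencies must be positive")
        if not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.impedance)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.impedance))

    # -- CSV round trip -----------------------------------------------------
    # header: frequency_hz,z_real_ohm,z_imag_ohm; '#'-prefixed metadata lines.

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            if self.timestamp is not None:
                fh.write(f"# timestamp_h: {self.timestamp}\n")
            if self.label is not None:
                fh.write(f"# label: {self.label}\n")
            fh.write("frequency_hz,z_real_ohm,z_imag_ohm\n")
            for f, z in zip(self.frequencies, self.impedance):
                fh.write(f"{f:.10g},{z.real:.10g},{z.imag:.10g}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        timestamp = None
        label = None
        body_lines = []
        with open(path) as fh:
            for line in fh:
                stripped = line.strip()
                if stripped.startswith("#"):
                    key, _, value = stripped.lstrip("# ").partition(":")
                    key = key.strip().lower()
                    if key == "timestamp_h":
                        timestamp = float(value)
                    elif key == "label":
                        label = value.strip()
                elif stripped:
                    body_lines.append(line)
        df = pd.read_csv(io.StringIO("".join(body_lines)))
        expected = {"frequency_hz", "z_real_ohm", "z_imag_ohm"}
        if not expected.issubset(df.columns):
            raise ValueError(
                f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}"
            )
        z = df["z_real_ohm"].to_numpy() + 1j * df["z_imag_ohm"].to_numpy()
        return cls(df["frequency_hz"].to_numpy(), z,
                   timestamp=timestamp, label=label)


def cpe_impedance(omega: np.ndarray | float, q: float, n: float) -> np.ndarray | complex:
    """Impedance of a constant phase element, ``1/(Q (j omega)^n)``.

    The phase is ``-n * 90°`` at every frequency and the modulus is
    ``1/(Q omega^n)``.

    Parameters
    ----------
    omega : float or array
        Angular frequency, rad/s.  Strictly positive.
    q, n : float
        CPE magnitude (S·sⁿ) and exponent in (0, 1].
    """
    scalar = np.ndim(omega) == 0
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if not np.all(omega > 0):
        raise ValueError("omega must be positive")
    _check_cpe(q, n)
    z = 1.0 / (q * (1j * omega) ** n)
    return complex(z[0]) if scalar else z


def circuit_impedance(freq: np.ndarray | float,
                      params: CircuitParams) -> np.ndarray | complex:
    """Complex impedance of Rsol + (CPE || Rct) at linear frequency `freq` (Hz)."""
    scalar = np.ndim(freq) == 0
    freq = np.atleast_1d(np.asarray(freq, dtype=float))
    if not np.all(freq > 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * freq
    z = params.rsol + params.rct / (
        1.0 + params.q * (1j * omega) ** params.n * params.rct
    )
    return complex(z[0]) if scalar else z


def simulate_spectrum(params: CircuitParams,
                      frequencies: np.ndarray,
                      timestamp: float | None = None,
                      label: str | None = None) -> Spectrum:
    """Noise-free forward-model spectrum on the given frequency grid."""
    return Spectrum(frequencies, circuit_impedance(frequencies, params),
                    timestamp=timestamp, label=label)


def cdl_from_cpe(q: float, n: float, rct: float) -> float:
    """Double-layer capacitance from CPE parameters: ``(Q Rct)^(1/n) / Rct``.

    Evaluated in log space, ``exp((ln Q + ln Rct)/n - ln Rct)``, so small
    exponents do not overflow.  Reduces exactly to ``Q`` at ``n = 1``.
    """
    _check_cpe(q, n)
    if not rct > 0:
        raise ValueError(f"Rct must be positive, got {rct!r}")
    if n == 1.0:
        return q
    return float(np.exp((np.log(q) + np.log(rct)) / n - np.log(rct)))


def q_from_cdl(cdl: float, n: float, rct: float) -> float:
    """Invert the Cdl estimate: the Q giving this Cdl at fixed n, Rct."""
    if not cdl > 0:
        raise ValueError("Cdl must be positive")
    if not rct > 0:
        raise ValueError("Rct must be positive")
    if not 0 < n <= 1:
        raise ValueError("n must lie in (0, 1]")
    # Cdl = (Q Rct)^(1/n) / Rct  =>  Q = (Cdl Rct)^n / Rct
    return float(np.exp(n * (np.log(cdl) + np.log(rct)) - np.log(rct)))


Kind = Literal["resistance", "capacitance"]


def area_normalize(value: float | np.ndarray, area: float, kind: Kind):
    """Convert a raw Ω or F value to its area-scaled form (Ω·cm² or F·cm⁻²).

    Resistances scale up with area (Ω → Ω·cm², multiply), capacitances scale
    down (F → F·cm⁻², divide); `area_denormalize` inverts exactly.
    """
    if not area > 0:
        raise ValueError(f"area must be positive, got {area!r}")
    if kind == "resistance":
        return value * area
    if kind == "capacitance":
        return value / area
    raise ValueError(f"kind must be 'resistance' or 'capacitance', got {kind!r}")


def area_denormalize(value: float | np.ndarray, area: float, kind: Kind):
    """Inverse of :func:`area_normalize`."""
    if not area > 0:
        raise ValueError(f"area must be positive, got {area!r}")
    if kind == "resistance":
        return value / area
    if kind == "capacitance":
        return value * area
    raise ValueError(f"kind must be 'resistance' or 'capacitance', got {kind!r}")


def parallel_capacitance(spectrum: Spectrum) -> np.ndarray:
    """Equivalent parallel capacitance per frequency, ``-Im(Z)/(omega |Z|^2)``.

    This is the imaginary part of the admittance divided by omega; for a pure
    capacitor it returns C at every frequency, for a pure resistor zero.
    """
    mod2 = np.abs(spectrum.impedance) ** 2
    if np.any(mod2 == 0):
        raise ValueError("zero-modulus impedance point: capacitance undefined")
    omega = 2.0 * np.pi * spectrum.frequencies
    return -spectrum.impedance.imag / (omega * mod2)


def modulus_phase(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """(|Z| in Ω, phase in degrees) per frequency point."""
    return spectrum.modulus, spectrum.phase_deg


def log_frequency_grid(f_min: float = 1.0, f_max: float = 1e6,
                       points_per_decade: int = 10) -> np.ndarray:
    """Logarithmic frequency grid, inclusive of both endpoints."""
    if not (f_min > 0 and f_max > f_min):
        raise ValueError("need 0 < f_min < f_max")
    n_decades = np.log10(f_max / f_min)
    n_pts = int(round(n_decades * points_per_decade)) + 1
    return np.logspace(np.log10(f_min), np.log10(f_max), n_pts)
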