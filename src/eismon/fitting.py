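"""Complex nonlinear least-squares estimation of equivalent-circuit parameters.

The estimator fits ``Z(f) = Rsol + Rct / (1 + Q (j 2 pi f)^n Rct)`` to a
measured spectrum by minimizing the stacked, weighted real/imaginary
residuals with a bounded trust-region solver.  Because impedance moduli span
several decades between 1 Hz and 1 MHz, the default weighting divides each
residual by the measured modulus ("modulus" weighting), so every frequency
point contributes comparably to the objective.

Rsol, Rct and Q are optimized in log space (positivity for free and well
conditioned across their natural scales); ``n`` is bounded in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .circuit import CircuitParams, Spectrum, cdl_from_cpe, circuit_impedance
from .series import MonitoringSeries

__all__ = [
    "EquivalentCircuitFitter",
    "FitResult",
    "IdentifiabilityError",
    "initial_guess",
    "fit_spectrum",
    "fit_series",
    "DEFAULT_FALLBACK_PARAMS",
]

#: Scenario-neutral initialization used when every other guess fails.
DEFAULT_FALLBACK_PARAMS = CircuitParams(rsol=100.0, rct=1e4, q=1e-5, n=0.9)

WEIGHTINGS = ("unit", "modulus", "proportional")


class IdentifiabilityError(ValueError):
    """The spectrum carries no information about the circuit parameters."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of one spectrum fit.

    ``params`` is ``None`` only for per-timepoint failures inside
    :func:`fit_series`; a non-converged single fit still reports its best
    iterate.  ``param_uncertainties`` are approximate standard errors from
    the Jacobian-based covariance at the optimum.
    """

    params: Optional[CircuitParams]
    param_uncertainties: dict
    cdl: float
    chi_sq: float
    n_iter: int
    converged: bool
    weighting: str
    message: str = ""

    @classmethod
    def failure(cls, message: str, weighting: str = "modulus") -> "FitResult":
        return cls(params=None, param_uncertainties={}, cdl=np.nan,
                   chi_sq=np.nan, n_iter=0, converged=False,
                   weighting=weighting, message=message)


def initial_guess(spectrum: Spectrum,
                  rct_floor: float = 1.0,
                  area: float | None = None) -> CircuitParams:
    """Heuristic starting parameters read off the spectrum's Bode shape.

    Rsol from the high-frequency modulus, Rct from the low-frequency plateau,
    the CPE exponent from the mid-frequency log-log slope of ``|Z - Rsol|``,
    and Q by inverting the CPE modulus at the midpoint of that region.
    """
    if len(spectrum) < 4:
        raise ValueError("initial_guess needs at least 4 frequency points")
    f = spectrum.frequencies
    if f[-1] / f[0] < 10:
        raise ValueError("spectrum must span at least one decade of frequency")
    mod = spectrum.modulus

    rsol0 = float(mod[-1])
    rct0 = float(mod[0]) - rsol0
    if rct0 < rct_floor:
        warnings.warn(
            "low-frequency plateau indistinguishable from Rsol; "
            f"Rct floored at {rct_floor} Ohm", RuntimeWarning, stacklevel=2)
        rct0 = rct_floor

    # mid-frequency CPE-dominated region: where the interfacial branch is
    # neither fully blocked nor shorted
    branch = np.abs(spectrum.impedance - rsol0)
    sel = (branch > 0.05 * rct0) & (branch < 0.95 * rct0) & (branch > 0)
    if sel.sum() < 2:
        k = len(f) // 3
        sel = np.zeros(len(f), bool)
        sel[k:max(2 * k, k + 2)] = True
        sel &= branch > 0
    if sel.sum() >= 2:
        slope = np.polyfit(np.log10(f[sel]), np.log10(branch[sel]), 1)[0]
        n0 = float(np.clip(-slope, 0.05, 1.0))
    else:
        n0 = 0.9

    idx = np.flatnonzero(sel)
    mid = idx[len(idx) // 2] if idx.size else len(f) // 2
    omega_mid = 2 * np.pi * f[mid]
    zb = branch[mid] if branch[mid] > 0 else mod[mid]
    q0 = 1.0 / (zb * omega_mid ** n0)

    kwargs = {} if area is None else {"area": area}
    return CircuitParams(rsol=max(rsol0, 0.0), rct=rct0, q=q0, n=n0, **kwargs)


def _residual_weights(spectrum: Spectrum, weighting: str) -> np.ndarray:
    """Per-point weights applied to both real and imaginary residuals."""
    if weighting == "unit":
        return np.ones(len(spectrum))
    if weighting == "modulus":
        return 1.0 / spectrum.modulus
    if weighting == "proportional":
        re = np.maximum(np.abs(spectrum.impedance.real), 1e-30)
        im = np.maximum(np.abs(spectrum.impedance.imag), 1e-30)
        return np.stack([1.0 / re, 1.0 / im])  # separate component weights
    raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")


class EquivalentCircuitFitter(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator for the Rsol + (CPE || Rct) circuit.

    ``fit(X, y)`` takes frequencies in Hz (``X``, shape ``(n,)`` or
    ``(n, 1)``) and complex impedance in Ω (``y``); ``predict(X)`` evaluates
    the fitted circuit.  Fitted attributes carry a trailing underscore
    (``rsol_``, ``rct_``, ``q_``, ``n_``, ``cdl_``, ``params_`` ...).

    Parameters
    ----------
    weighting : {"modulus", "unit", "proportional"}
        Residual weighting; "modulus" (default) divides residuals by
        ``|Z_meas|`` so decades-spanning spectra are fitted evenly.
    init : CircuitParams or None
        Starting point; ``None`` derives one with :func:`initial_guess`.
    ftol : float
        Relative function-value tolerance of the trust-region solver.
    max_iter : int
        Cap on objective evaluations before declaring non-convergence.
    area : float
        Electrode area (cm²) attached to the fitted parameters.
    """

    def __init__(self, weighting: str = "modulus",
                 init: Optional[CircuitParams] = None,
                 ftol: float = 1e-10, max_iter: int = 500,
                 area: float = 0.06):
        self.weighting = weighting
        self.init = init
        self.ftol = ftol
        self.max_iter = max_iter
        self.area = area

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _unpack(x: np.ndarray) -> tuple[float, float, float, float]:
        return np.exp(x[0]), np.exp(x[1]), np.exp(x[2]), x[3]

    def _validate_xy(self, X, y) -> Spectrum:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        y = np.asarray(y, dtype=complex)
        return Spectrum(X, y)

    def fit(self, X, y) -> "EquivalentCircuitFitter":
        """Estimate circuit parameters from frequencies `X` and impedance `y`."""
        spectrum = self._validate_xy(X, y)
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        mod = spectrum.modulus
        if np.ptp(mod) <= 1e-12 * mod.max() and np.ptp(spectrum.phase_deg) <= 1e-9:
            raise IdentifiabilityError(
                "constant spectrum: interfacial parameters are unidentifiable")

        init = self.init
        if init is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                init = initial_guess(spectrum, area=self.area)

        w = _residual_weights(spectrum, self.weighting)
        if w.ndim == 2:
            w_re, w_im = w
        else:
            w_re = w_im = w
        f = spectrum.frequencies
        omega = 2 * np.pi * f
        z_meas = spectrum.impedance

        def residuals(x):
            rsol, rct, q, n = self._unpack(x)
            z = rsol + rct / (1.0 + q * (1j * omega) ** n * rct)
            d = z - z_meas
            return np.concatenate([w_re * d.real, w_im * d.imag])

        x0 = np.array([np.log(max(init.rsol, 1e-6)), np.log(init.rct),
                       np.log(init.q), init.n])
        lb = np.array([np.log(1e-9), np.log(1e-9), np.log(1e-18), 0.05])
        ub = np.array([np.log(1e9), np.log(1e12), np.log(1.0), 1.0])
        x0 = np.clip(x0, lb, ub)

        sol = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                            ftol=self.ftol, xtol=1e-12, gtol=1e-12,
                            max_nfev=self.max_iter)

        rsol, rct, q, n = self._unpack(sol.x)
        self.params_ = CircuitParams(rsol=rsol, rct=rct, q=q, n=n,
                                     area=self.area)
        self.rsol_, self.rct_, self.q_, self.n_ = rsol, rct, q, n
        self.cdl_ = cdl_from_cpe(q, n, rct)
        self.chi_sq_ = float(2.0 * sol.cost)  # sum of squared weighted residuals
        self.n_iter_ = int(sol.nfev)
        self.converged_ = bool(sol.status > 0)
        self.message_ = sol.message
        self.param_uncertainties_ = self._uncertainties(sol, (rsol, rct, q, n))
        return self

    def _uncertainties(self, sol, raw: tuple) -> dict:
        """Approximate standard errors from the Jacobian at the optimum."""
        m, p = sol.jac.shape
        names = ("rsol", "rct", "q", "n")
        if m <= p:
            return {k: np.nan for k in names}
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * (2.0 * sol.cost) / (m - p)
            se_internal = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return {k: np.nan for k in names}
        # first three coordinates are logs: se(param) ~ param * se(log param)
        se = [raw[i] * se_internal[i] for i in range(3)] + [se_internal[3]]
        return dict(zip(names, se))

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted circuit at frequencies `X` (Hz)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit the estimator before calling predict")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X.ravel()
        return circuit_impedance(X, self.params_)

    def result_(self) -> FitResult:
        """Package the fitted state as a :class:`FitResult`."""
        return FitResult(params=self.params_,
                         param_uncertainties=self.param_uncertainties_,
                         cdl=self.cdl_, chi_sq=self.chi_sq_,
                         n_iter=self.n_iter_, converged=self.converged_,
                         weighting=self.weighting, message=self.message_)


def fit_spectrum(spectrum: Spectrum,
                 init: Optional[CircuitParams] = None,
                 weighting: str = "modulus",
                 area: float = 0.06,
                 **kwargs) -> FitResult:
    """Fit one spectrum; thin wrapper over :class:`EquivalentCircuitFitter`."""
    est = EquivalentCircuitFitter(weighting=weighting, init=init, area=area,
                                  **kwargs)
    est.fit(spectrum.frequencies, spectrum.impedance)
    return est.result_()


def fit_series(series: MonitoringSeries,
               warm_start: bool = True,
               weighting: str = "modulus",
               area: float = 0.06,
               **kwargs) -> MonitoringSeries:
    """Fit every timepoint of a series, attaching a FitResult per spectrum.

    With ``warm_start`` each timepoint initializes from the previous
    converged parameters; on failure it falls back to a fresh
    :func:`initial_guess` and finally to the scenario-neutral default.
    Per-timepoint failures are recorded as failed results, never raised.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    fits: list[FitResult] = []
    prev: Optional[CircuitParams] = None
    for spec in series.spectra:
        result = None
        inits: list[Optional[CircuitParams]] = []
        if warm_start and prev is not None:
            inits.append(prev)
        inits.extend([None, DEFAULT_FALLBACK_PARAMS.replace(area=area)])
        err = ""
        for init in inits:
            try:
                result = fit_spectrum(spec, init=init, weighting=weighting,
                                      area=area, **kwargs)
            except (ValueError, IdentifiabilityError) as exc:
                err = str(exc)
                continue
            if result.converged:
                break
        if result is None:
            result = FitResult.failure(err or "all initializations failed",
                                       weighting=weighting)
        fits.append(result)
        if result.converged and result.params is not None:
            prev = result.params
    series.fits = fits
    return series
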