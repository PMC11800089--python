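# Methods

## The measurement and the model

`eismon` analyzes electrochemical impedance spectroscopy (EIS) recordings of
plant callus growing on a pair of planar gold electrodes (two-electrode
configuration, 6 mm² per electrode). Each recording is a sweep of complex
impedance Z(f) from 1 Hz to 1 MHz, repeated hourly over a week, alongside
daily mass measurements of the same cultures.

The cell is modelled as a Randles-type equivalent circuit: a solution
(spreading) resistance `Rsol` in series with the lumped electrode/electrolyte
interface, itself a constant phase element (CPE) in parallel with a charge
transfer resistance `Rct`:

```
Z(ω) = Rsol + Rct / (1 + Q (jω)^n Rct),      Z_CPE(ω) = 1 / (Q (jω)^n)
```

with `0 < n ≤ 1`. At `n = 1` the CPE is an ideal capacitor and the circuit is
the textbook single-RC Randles form. The effective double-layer capacitance
is derived from the CPE parameters as

```
Cdl = (Q · Rct)^(1/n) / Rct
```

evaluated in log space (`exp((ln Q + ln Rct)/n − ln Rct)`) so small exponents
cannot overflow; at `n = 1` it reduces exactly to `Q`.

Assumptions worth stating:

* **Single time constant.** The two electrode interfaces are lumped into one
  CPE ∥ Rct branch. No Warburg/diffusion element, no inductive artifacts, no
  Kramers–Kronig validation.
* **Sign convention.** Capacitive reactance is negative imaginary
  (`Z = Z′ + jZ″`, `Z″ ≤ 0`); file I/O is in Hz, all formulas use `ω = 2πf`.
* **Area convention.** All computation is in raw Ω and F. Area-scaled
  figures (Ω·cm², μF·cm⁻²) are a reporting conversion using one electrode's
  geometric area, 0.06 cm² by default, configurable. Whether published
  area-scaled values used one or both electrodes' area is not knowable from
  the reported setup; one electrode is the package's convention.

## Fitting

`EquivalentCircuitFitter` estimates `(Rsol, Rct, Q, n)` by complex nonlinear
least squares: the real and imaginary residuals are stacked and minimized
jointly with a bounded trust-region solver (`scipy.optimize.least_squares`,
`ftol = 1e-10`, ≤ 500 evaluations). `Rsol`, `Rct`, `Q` are optimized in log
space, which enforces positivity and conditions the problem across their
natural scales (Ω to sub-μS); `n` is bounded in `[0.05, 1]`.

* **Weighting.** Default "modulus": each residual is divided by `|Z_meas|`,
  so a spectrum spanning four decades of modulus is fitted evenly. This is
  the standard choice for proportional measurement noise; "unit" and
  per-component "proportional" weighting are available. On noise-free data
  all weightings converge to the same optimum (tested to 0.01%).
* **Initialization.** `Rsol₀` from the high-frequency modulus, `Rct₀` from
  the low-frequency plateau (floored at 1 Ω with a warning for degenerate
  flat spectra), `n₀` from the mid-frequency log-log slope of `|Z − Rsol₀|`,
  `Q₀` by inverting the CPE modulus at the middle of that region.
* **Series fits** warm-start each timepoint from the previous converged
  parameters, falling back to a fresh heuristic guess and finally to a
  neutral default (100 Ω, 10 kΩ, 10 μS·sⁿ, n = 0.9). A failed timepoint is
  recorded and skipped, never fatal.
* **Uncertainties** are approximate standard errors from the Jacobian-based
  covariance at the optimum (residual variance scaled); no bootstrap.
* **Degenerate inputs.** A strictly constant spectrum raises an
  identifiability error; non-convergence is reported as a flag, not an
  exception.

## Growth analytics

* **Impedance extraction** at a target frequency (defaults 10 Hz and
  0.1 MHz) takes the grid point nearest in log-frequency, or log-log linear
  interpolation when the nearest point is more than 2% away. On a grid with
  8 and 12.5 Hz bracketing 10 Hz this yields the geometric mean of the two
  moduli.
* **Rates.** Linear rates are OLS slopes over a window; exponential rates
  are OLS on log-values, reported both as the rate constant (h⁻¹) and as the
  window-mean slope in base units per hour. The latter is the convention in
  which Rct growth rates are quoted (Ω·cm²/h), because those printed units
  are linear-slope units even though the trajectory is called exponential.
  Default windows: impedance 24–144 h, mass 0–96 h, Rct growth 72–144 h
  (auxin-rich) or 96–168 h (auxin-free); all configurable. Rates are stored
  per hour; the reporting layer converts to per day where wanted.
* **Correlation.** Mass (24-hourly) is aligned to the hourly impedance grid
  by nearest-hour matching — no interpolation of mass. Both series are
  min-max normalized (`(X − Xmin)/(Xmax − Xmin)`) before Pearson
  correlation; normalization is affine, so it changes the plot, not r.
* **Controls** (medium-only series) are analyzed alongside, never
  subtracted. The drift check flags a control whose |Z| deviates from its
  initial value by more than 5% (configurable).

## The synthetic generator

No raw recordings of this kind are publicly deposited, so the generator
produces series with the reported statistical structure; it is first-class,
tested code, and every pipeline stage is validated against it.

Parameter trajectories (the named presets carry the reported values):

| quantity | auxin-rich | auxin-free | form |
|---|---|---|---|
| Cdl (μF/cm²) | 13.32 → 9.93 | 10.15 → 8.73 | linear over 0–168 h |
| Rct onset (h) | 72 | 96 | dip −10% to 48 h, plateau, then exponential |
| Rct rate (Ω·cm²/h) | 3 | 1.8 | window-mean slope of the exponential |
| Rsol drift (Ω/day) | 28 | 36.2 | linear from 100 Ω |
| mass rate (μg/h) | 12.8 | 8.1 | linear from 20 mg |

The exponential rate constant is calibrated so the mean slope over the
growth window (72–144 h or 96–168 h) equals the quoted Ω·cm²/h figure; the
trajectory is continuous at every breakpoint. `Q` is back-solved from the
Cdl formula at each timepoint. The same rates have also been quoted in
kΩ·cm²/h; both unit readings are preserved
(`scenario_preset(..., rct_rate_convention="discussion")`), defaulting to
the Ω·cm²/h reading, and no intent is guessed between them.

Values the source material does not report, chosen once:

* `rct_baseline = 10⁴ Ω·cm²` and `n_cpe = 0.9`: give |Z|@10 Hz in the
  tens-of-kΩ range consistent with the described kΩ-scale low-frequency
  signals; clearly labelled non-reported and configurable.
* `rsol_start = 100 Ω`: typical for a two-electrode cell in ~1 mL of culture
  medium.
* **Noise.** Spectra: independent Gaussian noise on real and imaginary
  parts with σ = 1% of |Z| (proportional noise matches modulus-weighted
  fitting). Mass: additive Gaussian with σ = 0.2 mg, set so that the
  noise-to-range ratio of a week-long mass trajectory reproduces the
  strength of the published mass–impedance correlations (r ≈ 0.95).
* **Determinism.** One root seed derives an independent child stream per
  (kind, timepoint) via `SeedSequence((seed, stream, index))`, so extending
  a series never reshuffles earlier draws; identical seeds give bit-identical
  output.

What the generator does **not** emulate: electrode fouling and drift
artifacts, temperature effects, mucilage multilayers, the quasi-periodic
high-frequency oscillations seen in real recordings, replicate-to-replicate
biological variability. Passing recovery tests therefore demonstrates that
the estimator and analytics are correct and well-conditioned under the
assumed noise model — not that real recordings obey the model.

## Problem sizes and numerical checks

The default verification runs use: the full 169-spectrum week at 1 h
spacing for round-trip fitting (noise-free recovery is at machine precision,
< 10⁻¹³ relative); 30 independent seeds for the noisy (1%) recovery study,
in which the across-seed means of the fitted Cdl endpoints and the OLS mass
slope are compared to the generating values (a single seed's mass slope from
five 24-hourly points has a standard error of ~2.6 μg/h, so per-seed
agreement is not a meaningful criterion); and 10 seeds for the Rct-rate
recovery, which needs per-timepoint fits across the growth window.
Condition discrimination (auxin-rich impedance rate > auxin-free) is
evaluated on 30 independent seed pairs.

## Known limitations

* Single-time-constant topology only; no model selection across circuits.
* Pearson values on synthetic data depend on the assumed mass noise; the
  auxin-free preset, with its shallower trend, yields r ≈ 0.88 rather than
  the published 0.95 — absolute levels on synthetic data are indicative,
  not reproductions.
* Fit uncertainties are asymptotic (Jacobian-based) and can be optimistic
  near the `n = 1` bound.
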