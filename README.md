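# eismon

Equivalent-circuit impedance spectroscopy (EIS) analytics for real-time,
label-free monitoring of in vitro plant callus growth.

## The problem

Micropropagation workflows (e.g. somatic embryogenesis of tree crops) need
non-destructive, real-time readouts of callus growth and physiological
state. Hourly impedance sweeps of callus sitting on a pair of planar gold
electrodes provide exactly that: as cells adhere and the cell layer
thickens, the interfacial capacitance falls and the low-frequency impedance
rises in step with biomass. `eismon` turns such recordings — a week of
hourly 1 Hz–1 MHz sweeps plus daily mass measurements — into circuit
parameters, growth rates, and impedance–mass correlations. It is aimed at
bioelectrochemistry and plant-biotech groups who today push each sweep
through a GUI fitting tool by hand.

## The model

Each sweep is fitted with a Randles-type equivalent circuit: a solution
resistance in series with a constant phase element (CPE) in parallel with a
charge transfer resistance,

```
Z(ω) = Rsol + Rct / (1 + Q (jω)^n Rct),          0 < n ≤ 1,
```

by weighted complex nonlinear least squares (stacked real/imaginary
residuals, modulus weighting, bounded trust-region solver). The effective
double-layer capacitance follows from the CPE parameters,

```
Cdl = (Q · Rct)^(1/n) / Rct,
```

and the time courses of `|Z|` at 10 Hz and 0.1 MHz, `Cdl`, `Rct`, `Rsol`
and mass are reduced to windowed rates (OLS or log-linear), min-max
normalized trajectories, and Pearson correlations. Because no raw
recordings of this kind are publicly deposited, the package ships a seeded
synthetic generator whose presets (`auxin_rich`, `auxin_free`,
`medium_only`) encode the reported parameter trajectories, so the whole
pipeline is testable end to end. See `docs/methods.md` for the details and
assumptions.

## Worked example

```bash
eismon simulate --scenario auxin_rich  --seed 7 --out rich
eismon simulate --scenario medium_only --seed 8 --out ctrl
eismon monitor rich --control ctrl --out report
```

prints (alongside `report/report.json`, `fits.csv`, `impedance.csv`):

```
condition: auxin_rich
fits: 169/169 converged
|Z| rate @ low freq: 39.1 ohm/h (937 ohm/day), R2=0.964, window [24.0, 144.0] h
mass rate: 14.2 ug/h, R2=0.818, window [0.0, 96.0] h
mass-impedance Pearson r: 0.957 (n=8, p=0.00019)
r_Rct: 3.08 ohm cm2/h (window [72.0, 144.0] h)
Cdl: 13.3 -> 9.942 uF/cm2 (25.2% decline)
|Z| vs Cdl regression: R2=0.976
control: stable (max relative deviation 3.50%, threshold 5%)
```

Reading the numbers: all 169 hourly spectra were fitted; the 10 Hz
impedance climbs at ~39 Ω/h over the 24–144 h analysis window while the
high-frequency channel barely moves; the mass slope over the first 96 h
(14.2 μg/h here, truth 12.8 μg/h ± noise) tracks the normalized impedance
with Pearson r = 0.96; the charge-transfer resistance grows at
~3 Ω·cm²/h after its 72 h onset; the double-layer capacitance declines ~25%
over the week; and the medium-only control stays within the 5% stability
band, so the signal is attributable to the cells.

The same machinery is available as a library; the fitting core is a
scikit-learn-style estimator:

```python
import eismon as em

scenario = em.scenario_preset("auxin_rich", seed=7)
series = em.simulate_series(scenario)

est = em.EquivalentCircuitFitter()
est.fit(series.spectra[0].frequencies, series.spectra[0].impedance)
print(est.rsol_, est.rct_, est.n_, est.cdl_)

report = em.run_monitor(series)
```

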