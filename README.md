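# thermocap

Heat capacities from molecular-dynamics energy time series — and what they
can (and cannot) say about enzyme catalysis and ligand binding.

## The problem

Curved Arrhenius plots and enzyme temperature optima below the melting
point are sometimes attributed to a negative *activation heat capacity*
ΔCp‡ = Cp(TS) − Cp(ES).  Testing that hypothesis computationally requires
absolute heat capacities of solvated systems from plain MD, which can be
done two ways:

* **derivative formula** — Cp = ∂⟨E_tot⟩/∂T, the slope of the mean total
  energy across a few temperature setpoints;
* **fluctuation formula** — Cp = ⟨δE_tot²⟩/(R·T²) at each setpoint.

The catch is the thermostat: weak-coupling (Berendsen) dynamics suppresses
energy fluctuations — increasingly so for larger relaxation times τ — so
the fluctuation route silently underestimates Cp, while the derivative
route is robust for every common thermostat.  `thermocap` implements both
estimators with their error protocols (two-block averaging, regression
standard error, s.e.m. across temperatures), the difference/cycle
bookkeeping for activation and binding heat capacities, the curved-
Arrhenius (MMRT) model

    ΔG‡(T) = ΔH‡(T0) − T·ΔS‡(T0) + ΔCp‡·[(T − T0) − T·ln(T/T0)]

with Eyring/van't Hoff transforms, and synthetic thermostatted dynamics
(an analytic harmonic lattice plus a compact rigid-TIP3P periodic-box MD
engine) that reproduce the thermostat artifacts on demand.

## Worked example

```python
from thermocap import (TemperatureEnsemble, ThermostatConfig,
                       build_harmonic_lattice, simulate,
                       cp_derivative, cp_fluctuation)

lattice = build_harmonic_lattice(64)          # analytic Cv = 3nR = 0.3815
ens = TemperatureEnsemble(tuple(
    simulate(lattice, ThermostatConfig("berendsen", tau=1000.0),
             T, n_steps=60_000, seed=i)
    for i, T in enumerate((280, 290, 300, 310, 320))
))
der = cp_derivative(ens)
fl  = cp_fluctuation(ens)
print(f"derivative : {der.value:.4f} ± {der.err_block:.4f} kcal/mol/K")
print(f"fluctuation: {fl.value:.4f} ± {fl.err_sem:.4f} kcal/mol/K")
```

prints (seeds as above):

```
derivative : 0.3881 ± 0.0064 kcal/mol/K
fluctuation: 0.0056 ± 0.0052 kcal/mol/K
```

The derivative estimator lands on the exact equipartition value (0.3815)
within two block errors even under a deliberately weakly-coupled Berendsen
thermostat; the fluctuation estimator collapses by a factor of ~70 — the
thermostat artifact the package is built to expose.  `examples/` contains one short script per
capability (estimators, Berendsen artifact, activation/binding
differences, MMRT fitting, TIP3P water benchmark).

Energy series from real MD engines enter through `read_energy_table`
(delimited text) or `read_xvg` (GROMACS energy export), or from the shell:

```bash
thermocap cp --method derivative --component etot --in rundir/ --out cp.json
thermocap arrhenius --model eq1 --in points.csv
```

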