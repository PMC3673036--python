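# charkit

Quantitative characterization of protein kinase domains from standard
biophysical and biochemical assays. The package implements, as tested and
reusable model/results objects, the four analyses used to profile the
catalytic domains of the human EphB receptor tyrosine kinases
(EphB1–EphB4 plus the EphB3 C717G mutant):

1. **Thermal unfolding** — CD melts at 222 nm fitted with the
   six-parameter two-state van't Hoff model

   K(T) = exp[−ΔH<sub>m</sub>(1 − T/T<sub>m</sub>)/(R·T)],  
   Y(T) = [(a<sub>n</sub> + b<sub>n</sub>T) + (a<sub>u</sub> + b<sub>u</sub>T)·K] / (1 + K)

   giving the midpoint T<sub>m</sub> (°C) and van't Hoff enthalpy
   ΔH<sub>m</sub> (kJ/mol); DSF melts fitted with a Boltzmann sigmoid for
   T<sub>m</sub> and compound-induced ΔT<sub>m</sub> shifts.
2. **Chemical (GdnHCl) unfolding** — linear-extrapolation two-state and
   sequential three-state (N↔I↔U) models for intrinsic tryptophan
   fluorescence titrations, with small-sample Akaike (AICc) weights
   converting the fits into model probabilities that sum to 100%.
3. **Steady-state enzyme kinetics** — initial velocities from
   stopped-assay luminescence time courses, Michaelis–Menten regression
   (K<sub>m</sub>, V<sub>max</sub>), and turnover bookkeeping
   k<sub>cat</sub> = V<sub>max</sub>·M/6×10⁷ with specificity-constant
   (k<sub>cat</sub>/K<sub>m</sub>) comparisons across enzymes.
4. **Inhibitor dose-response profiling** — 384-well-style 12-point
   half-log plates normalized against max/min control wells and fitted
   with a four-parameter logistic for IC50, with out-of-window results
   reported as bounds ("> top dose") and tight-binding flags.

A seeded synthetic-data generator (`charkit.simulate`) produces
instrument-shaped datasets for every stage, parameterized by the
published characterization tables, so the entire pipeline is testable by
parameter-recovery experiments without any instrument files. A
configuration-driven pipeline (`charkit run config.yaml`) orchestrates
any subset of stages and emits per-stage reports plus a combined
enzyme × property summary.

Intended users: protein scientists and assay groups who want a scripted,
reproducible version of the Prism/Origin-style curve-fitting workflow
for stability and potency characterization.

## Worked example

```python
import numpy as np
from charkit import (published_presets, generate, ThermalUnfolding,
                     MichaelisMenten, DoseResponse)

# a noisy CD melt simulated at the EphB1 truth (Tm 59.7 °C, ΔHm 156.6 kJ/mol)
melt = generate(published_presets()["EphB1.thermal"].with_noise(sigma=0.01, seed=42))[0]
print(ThermalUnfolding(melt).fit().summary())

ds = generate(published_presets()["EphB1.kinetics"].with_noise(seed=42))[0]
print(MichaelisMenten.from_dataset(ds).fit().summary())

plate = generate(published_presets()["EphB4.CMPD1.ic50"].with_noise(seed=42))[0]
print(DoseResponse.from_plate(plate).fit().summary())
```

prints

```
Two-state van't Hoff thermal unfolding
  sample: EphB1.thermal   n = 61   converged = True
  Tm   =    59.504 ± 0.491 °C
  dHm  =    155.87 ± 5.55 kJ/mol
  folded baseline:   0.9923 + 0.0002474·T
  unfolded baseline: 0.0621 + -0.0008364·T
  RSS = 0.003761   R² = 0.99953

Michaelis–Menten fit
  enzyme: EphB1   n = 8   converged = True
  Km   =     544.2 ± 17.3
  Vmax =    1407.6 ± 13.7 nmol/min/mg
  kcat =     0.796 s⁻¹   kcat/Km = 0.00146
  R² = 0.99940

Four-parameter logistic dose-response fit
  compound: CMPD1   enzyme: EphB4   n = 12
  IC50 = 0.05812 μM   hill = 0.957
  top = 100.34%   bottom = -1.27%   R² = 0.9993
```

With 1% melt noise the fit recovers T<sub>m</sub> within ~0.2 °C and
ΔH<sub>m</sub> within a few kJ/mol of the generating truth; the kinetic
fit recovers K<sub>m</sub> = 544 μM against a truth of 555 μM (3% CV
noise), and the plate fit recovers an IC50 of 0.058 μM against a truth
of 0.062 μM. Standard errors come from the curvature of the
least-squares objective at the optimum.

The same stages are available from the shell:

```bash
charkit simulate --stage thermal --preset EphB1 --sigma 0.01 --seed 7 --out melts.csv
charkit fit-thermal melts.csv --report thermal_fits.csv
charkit run config.yaml     # multi-stage pipeline with reports + summary
```

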