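# sorptherm

Moisture-sorption isotherm fitting and sorption thermodynamics for food and
biopolymer powders.

The package fits a registry of ten classical sorption isotherm models
(Peleg, GAB, BET, Halsey, Oswin, Smith, Adam–Shove, modified Oswin, modified
Halsey, Dent) to equilibrium moisture data per branch and temperature, ranks
them by standard selection criteria (R² ≥ 0.90, mean relative percent error
< 10, minimum mean squared error), and derives:

- **spreading pressure** from a Dent fit anchored on the BET monolayer,
  with a closed form cross-validated against direct numerical quadrature;
- **isosteric heats** (net and integral), **differential entropy** and
  **Gibbs free energy** via Clausius–Clapeyron isostere regression at three
  or more temperatures, plus power/log/exponential trend fits;
- **enthalpy–entropy compensation** (isokinetic temperature vs. the
  harmonic mean temperature, with an enthalpy-/entropy-driven verdict);
- **Gordon–Taylor** glass-transition plasticization with critical storage
  moisture and the corresponding water activity;
- a **synthetic data generator** that emulates multi-temperature sorption
  experiments (type-III curves, hysteresis, duplicate replicates) and
  Clausius-consistent datasets whose true isosteric-heat profile is known
  by construction.

## Units

Moisture is g water / g dry matter (fraction form) everywhere; temperatures
are stored in kelvin (CSV input may declare Celsius); energies are J/mol
internally. Glass-transition work uses wet-basis mass fraction, converted
at the boundary.

## CLI

```sh
# generate a synthetic three-temperature dataset
sorptherm simulate --scenario default --seed 1 --out data.csv

# fit all models, write Table-style parameters.csv / criteria.csv
sorptherm fit --input data.csv --seed 20231226 --out results/

# spreading pressure, thermodynamics, glass transition, full report
sorptherm spread --input data.csv --out spread.csv
sorptherm thermo --input data.csv --out thermo/
sorptherm simulate --scenario tg --seed 1 --out tg.csv
sorptherm tg --input tg.csv --storage-temp 0 --out tg.json
sorptherm report --input data.csv --tg-csv tg.csv --seed 1 --out report.json
sorptherm config   # print defaults
```

Input CSV header: `branch,temperature,aw,xe` with
`branch ∈ {adsorption, desorption}`; `#` starts a comment line. The
glass-transition CSV header is `xw,tg_c`.

## Library example

```python
import numpy as np
from sorptherm import (
    AnalysisConfig, run_pipeline, default_scenario, generate_sorption,
    fit_all_models, rank_models,
)

dataset = generate_sorption(default_scenario(seed=1))
fits = fit_all_models(dataset, seed=1)
for branch in dataset.branches():
    ranking = rank_models([f for f in fits if f.branch is branch])
    print(branch.value, "->", ranking.best_model_id)

report = run_pipeline(AnalysisConfig(seed=1))
```
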