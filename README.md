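# acidflux

Dynamic flux balance analysis (dFBA) of fungal organic-acid batch
fermentation, built around a two-stage ("double") optimisation: every Euler
time-step first maximises growth, then — with growth pinned at its optimum —
maximises a secondary objective chosen by a phosphate-limitation test.
While external phosphate supply exceeds growth demand the surplus is stored
(polyphosphate pool); once growth becomes phosphate-limited the objective
switches to external proton production, which drives secretion of organic
acids through pH-dependent polyprotic dissociation reactions.  The switch
reproduces the diauxic onset of citrate production observed in batch
fermentations.

Features:

* **Network model** — stoichiometric networks with role-tagged special
  reactions (biomass, proton output, phosphate input/storage, sugar uptake,
  per-acid secretion + dissociation pairs, glucose oxidase, oxalate branch),
  biomass-composition adjustment (nucleic-acid / phospholipid scaling with
  glycerol mass balancing) and `oah` / `gox` gene knockouts.  A bundled,
  hand-checkable 23-reaction toy network (`make_toy_network`, documented in
  `src/acidflux/data/toy_network.md`) plus SBML L3+fbc import/export.
* **FBA core** — GLPK (swiglpk) reference backend with warm-started
  persistent problems for the simulation hot loop, a scipy/HiGHS fallback,
  and the two-stage optimisation with a deterministic degeneracy-breaking
  epsilon.
* **Kinetics** — Michaelis–Menten uptake bounds for external/stored
  phosphate, glucose (citrate-inhibited, low-affinity system active at
  ≥150 g/L), xylose, the forced pH-dependent glucose-oxidase flux, the 8-h
  phosphate-input switch, the initial-pH-dependent citrate cap and the
  below-pH-2 oxalate shut-off.
* **Acid chemistry** — per-acid fractional proton release as a function of
  ambient pH (seven acids, three dissociation constants each), with the
  external proton pool tracked dynamically.
* **Fitting** — weighted least squares against observed time-series
  (optionally across several experiments jointly), seeded multi-start
  Nelder–Mead, and AIC model ranking (`AIC = 2k + n·ln(RSS/n)`), plus a
  seeded synthetic-observation generator for recovery experiments.

## CLI

```bash
acidflux simulate --network toy --config examples/batch.yaml --out runs/batch
acidflux make-toy --out toy/                      # TSV + SBML + summary
acidflux synth-obs --config cfg.yaml --noise 0.02 --seed 1 --out obs.csv
acidflux fit --network toy --obs obs.csv --free v_Pe_max,K_Pe --seed 1
acidflux select --candidates variants.yaml --obs obs.csv --config cfg.yaml
```

A configuration file is YAML with three optional sections (all fields have
protocol defaults: 1/60 h steps, 18 h germination offset, 0.3125 g/L
initial biomass, 160 g/L glucose, pH 2):

```yaml
network: toy          # or a path to an SBML file
simulation:
  duration: 192.0
  phosphate_gL: 0.17
  initial_ph: 2.0
  knockouts: [oah]
parameters:
  v_CIT: 0.12
```

Trajectories are written as CSV (one row per step: time on the inoculation
clock, biomass, sugars, phosphate, stored phosphate, the seven acids, pH,
active objective, growth rate) with a JSON summary and a reproducibility
manifest.

## Layout

```
src/acidflux/
  network.py    stoichiometric model, toy fixture, adjustments, knockouts
  fba.py        LP backends + two-stage optimisation
  kinetics.py   uptake kinetics and event rules
  acids.py      polyprotic dissociation chemistry, proton pool
  engine.py     Euler dFBA loop, trajectories, diauxic switch detection
  fitting.py    RSS/AIC, Nelder-Mead fitting, model selection, synthetic data
  io.py         config validation, CSV/TSV/JSON writers, manifests
  cli.py        click command group
  data/         acid constants, toy network tables, parameter file
```
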