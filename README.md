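# flavopt

Chemometric optimization pipeline for ultrasonic extraction of total
flavonoids: Box–Behnken experimental design, quadratic response-surface
modeling with Type-III ANOVA and lack-of-fit, a feed-forward neural-network
surrogate with Garson weight-decomposition importance, genetic-algorithm and
particle-swarm global optimization, four-way factor-importance ranking
(Garson / F-test / random forest / gradient-boosted trees), radical-
scavenging assay statistics, and first-order extraction kinetics.

The package ships a published 29-run Box–Behnken extraction experiment
(four factors: extraction time, ethanol concentration, material-liquid
ratio, extraction power), the matching trained-network weight table and the
optimum-validation table as plain-CSV fixtures, plus seeded synthetic-data
generators with known ground truth for every input the pipeline consumes.

## Library overview

| Module | Contents |
| --- | --- |
| `flavopt.design` | `FactorSpec`, `DesignTable`, `build_bbd`, coded/natural conversion, CSV I/O |
| `flavopt.rsm` | `fit_quadratic`, `predict`, Type-III `anova`, `r_squared`, deterministic `optimize_on_cube` |
| `flavopt.ann` | 4→n→1 tansig/purelin network: `forward`, `train` (momentum GD, seeded restarts, test-MSE early stopping), weight-table I/O |
| `flavopt.importance` | `garson`, `f_test_rank`, in-package CART/`rf_importance`/`gbrt_importance`, `rank_table` |
| `flavopt.metaheuristics` | `ga_maximize`, `pso_maximize`, end-to-end `surrogate_optimize` |
| `flavopt.assays` | standard curve, flavonoid yield, DPPH/superoxide/hydroxyl scavenging |
| `flavopt.kinetics` | log-transform, linear first-order fit, Boltzmann nonlinear fit |
| `flavopt.synthetic_data` | seeded generators with exact zero-noise invertibility |
| `flavopt.datasets` | packaged fixtures |

```python
from flavopt import datasets, fit_quadratic, anova, optimize_on_cube

design = datasets.load_extraction_design()
model = fit_quadratic(design)          # 15-term quadratic on coded factors
table = anova(model, design)           # Type-III ANOVA with lack-of-fit
best = optimize_on_cube(model)         # deterministic box-constrained argmax
```

## Command line

All stages are exposed under a single `flavopt` entry point; `packaged` may
be passed wherever a design CSV is expected to use the bundled experiment.

```bash
flavopt design --factors factors.yaml --centers 5 -o design.csv
flavopt fit-rsm packaged -o model.json
flavopt anova packaged -o anova.json
flavopt train-ann packaged --hidden 2:12 --seed 7 -o ann.json
flavopt importance packaged --methods garson,f_test,rf,gbrt --seed 1 -o ranks.json
flavopt optimize packaged --surrogate ann --method ga --seed 7 --validate 14.0137
flavopt assays dpph measurements.csv
flavopt kinetics series.csv --c-inf auto
flavopt simulate bbd --noise 0.3 --seed 42 -o synth.csv
```

Reports are JSON with the package version and resolved configuration
embedded; exit codes distinguish parse failures (2) from numerical
failures (3).

## Notes

- The material-liquid ratio factor is parameterized by its denominator
  (mL solvent per g material), so a ratio of 1:15 sits at the coded +1 level.
- The packaged weight table is used as published; its input-bias column is
  symmetric about zero and its layer-weight column repeats values.
- Scavenging efficiencies are never clamped: values outside [0, 100] are
  flagged as suspect rather than silently truncated.
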