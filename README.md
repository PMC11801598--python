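# t2dcem

A transparent, tested two-arm Markov cohort cost-effectiveness model for
type 2 diabetes therapies: parallel complication sub-models (eye, lower
extremity, renal, IHD, MI, stroke, heart failure) plus a mortality engine,
risk-factor trajectories with an HbA1c-threshold treatment switch, cost and
QALY accrual with discounting, incremental cost-effectiveness with dominance
classification, and one-way plus probabilistic sensitivity analysis with
cost-effectiveness acceptability curves.

The bundled default parameterization compares a fixed-ratio basal
insulin/GLP-1RA combination (one daily injection) against GLP-1RA added to
basal insulin (two daily injections) in a Chinese type 2 diabetes cohort
over a 30-year horizon with 5% annual discounting, all costs in 2022 CNY.

## Layout

| module | purpose |
| --- | --- |
| `t2dcem.parameters` | config types, strict YAML loading/validation, bundled defaults |
| `t2dcem.risk_equations` | annual event-probability equations, risk-factor trajectories |
| `t2dcem.cohort_engine` | deterministic probability-mass propagation per arm |
| `t2dcem.economics` | cost/QALY ledgers, discounting, ICER/dominance summary |
| `t2dcem.uncertainty` | tornado analysis, second-order Monte Carlo PSA, CEAC |
| `t2dcem.synthetic_data` | toy sub-models with closed forms, perturbed configs |
| `t2dcem.reporting` / `t2dcem.cli` | output tables and the command line |

Model inputs live in `src/t2dcem/data/default_config.yaml` (single source of
truth) and `src/t2dcem/data/risk_coefficients.csv` (equation coefficients,
config-overridable via the `risk_coefficients` key).

## CLI

```sh
t2dcem validate                       # check a config (default: bundled)
t2dcem base-case --out-dir out/       # incidence / cost / base-case tables
t2dcem owsa --out-dir out/            # tornado CSV (default: built-in ranges)
t2dcem psa --n-draws 1000 --seed 0 --out-dir out/   # scatter + CEAC CSVs
```

All commands accept `--config path/to/config.yaml`; outputs are plain CSV
plus a `metadata.yaml` carrying the config hash and seed.

## Notes on conventions

- Cycle length is one year; covariates are start-of-cycle values.
- Mortality is applied before sub-model transitions within a cycle; event
  costs accrue in the transition cycle, state costs in every occupied cycle
  including the event cycle.
- Discounting defaults to an undiscounted first cycle (`(1+r)^-t`, t from
  0); `econ.discount_from_cycle_one` switches conventions, and
  `econ.half_cycle_correction` enables start/end-of-cycle averaging.
- Utilities combine additively (baseline + decrements) with a floor at 0.
- PSA: beta for utilities, gamma for costs (default SE = 10% of mean),
  normal for between-arm effects (sd = CI width / 3.92), drawn independently
  in sorted-parameter order from one seeded generator.
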