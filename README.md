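# sevocea

Bayesian cost-effectiveness analysis of adding domiciliary topical
sevoflurane to conventional analgesia for painful, nonrevascularizable leg
ulcers — packaged as a reusable, tested pipeline:

1. **records** — typed data model for three record levels (patients,
   pain visits, resource use) with delimited-text I/O, an XLSX ingestion
   shim, and cohort validation;
2. **outcomes** — SPID (sum of pain intensity differences, month-weighted
   over a 12-month horizon), last-observation carry-forward for patients
   who died or lost the leg, pain-reduction rate, oral-morphine
   equivalents, post hoc power, group descriptives;
3. **costing** — annual per-patient costs in reference-year euros (CPI
   adjusted), DRG admission tariffs with/without complications, and the
   one-way hospitalization variants (forced complication status,
   attribution-restricted admissions, per-diem);
4. **bayes** — bivariate Bayesian regression of (log annual cost, SPID) on
   six covariates via a from-scratch two-block Gibbs sampler with diffuse
   normal coefficient priors and a Wishart prior on the error precision;
5. **cea** — costs ratio `exp(beta_treat)`, incremental effectiveness,
   dominance probabilities, ICER (with a documented log-scale
   retransformation convention), cost-effectiveness plane and
   acceptability curve;
6. **sensitivity** — scenario suite: cost variants, event-exclusion
   subgroup, ±25% extreme scenario;
7. **synthetic** — study-shaped cohort generator with known ground truth,
   consistent across all three record levels, plus a parameter-recovery
   experiment;
8. **pipeline / cli** — one-command orchestration with a YAML config.

## CLI

```bash
# synthetic end-to-end run with the full scenario suite
sevocea all --out results/run1 --synthetic --seed 7

# or stage by stage
sevocea simulate --seed 7 --out results/sim
sevocea outcomes --patients results/sim/patients.csv --visits results/sim/visits.csv --out results/outcomes.csv
sevocea cost --patients results/sim/patients.csv --visits results/sim/visits.csv \
             --resources results/sim/resources.csv --out results/costs.csv
sevocea fit --rows results/sim/analysis_rows.csv --iterations 100000 --burn-in 10000 \
            --seed 7 --out results/posterior_summary.csv
sevocea cea --rows results/sim/analysis_rows.csv --out results/cea.json
```

`sevocea all` accepts a YAML config (`--config cfg.yaml`) with sections
`inputs` (or `synthetic`), `unit_costs`, `cpi`, `prior`, `mcmc`,
`scenarios`, `lambda_max`, `credible_level`; CLI flags override config
keys. The output bundle contains per-patient outcome and cost CSVs, the
posterior summary, the CEA summary JSON, CEAC/CE-plane data and figures,
the per-scenario collation, and a run log with the master seed — re-running
the same config is byte-identical on the data files.

To analyze real study data, supply the three delimited tables (headers
remappable via `column_map`) plus unit-cost/CPI tables; a single-workbook
deposit can be mapped with `sevocea.records.load_workbook_tables`, and
pre-aggregated per-patient (cost, SPID) columns can enter directly through
`sevocea.bayes.rows_from_frame`, bypassing the outcomes/costing stages.

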