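# eqaplan

Planning toolkit for the participation of human-genetics laboratories in
external quality assessment (EQA) schemes. It implements, as executable
rules:

* a **Bayesian binomial error-rate model** — Beta posterior under a
  noninformative prior (uniform or Jeffreys), upper credible bounds and the
  inverse question: the minimum annual test volume for a bounded error
  rate. At the defaults (1% threshold, 95% one-sided, uniform prior, zero
  errors) the continuous solution is ln(0.05)/ln(0.99) − 1 ≈ 297.07, so
  nearest-integer rounding gives **297 tests/year** (a strict-ceiling mode
  gives 298). t-based confidence intervals of literature mean error rates
  are also provided;
* a **rule-based multi-year participation planner**: annual coverage of
  every technique (virtual schemes count), a triennial exemption for
  high-volume, long-validated, stable methods, triennial
  genotyping/interpretation coverage per clinical indication in rolling
  3-year windows, mandatory next-year participation after genotyping or
  critical-interpretation errors, and CAPA-documentation checks. The
  planner selects fee-minimal schedules (globally optimal dynamic program
  on small instances, greedy weighted set cover otherwise) and an
  **independent auditor** verifies any plan or history;
* **cost-scenario budgeting**: exact integer-cent fee aggregation, percent
  reductions between scenarios, per-center budget shares;
* **seeded synthetic fixtures** emulating a 90-scheme / 72-indication
  inventory with scope-category mix 65/21/1/1/1/1 and 15 multi-provider
  indications, plus center profiles and participation histories.

## CLI

```sh
# minimum annual volume for a 1% error-rate bound (prints 297)
eqaplan minn --threshold 0.01 --level 0.95 --prior uniform --sided upper

# t-based CI of a mean error rate from summary statistics
eqaplan meta-ci --n 7 --mean 0.89 --sd 0.82

# generate a synthetic inventory, center profiles and history
eqaplan simulate --seed 1 --out sim/

# cost-minimal compliant plan, written to plan.csv + report.txt
eqaplan plan --inventory sim/schemes.csv --center sim/center_1.yaml \
    --history sim/history.csv --years 2024:2026 --out out/

# audit a plan (or a raw history); nonzero exit if anything is overdue
eqaplan audit --inventory sim/schemes.csv --center sim/center_1.yaml \
    --history sim/history.csv --plan out/plan.csv --window 2024:2026

# scenario comparison (reductions in %, nearest integer)
eqaplan budget --plan out/plan.csv --inventory sim/schemes.csv \
    --scenario-cost full=117400 --scenario-cost hist=82000
```

## File formats

* `schemes.csv` — columns `scheme_id, provider, indication, techniques,
  scope_technique, scope_genotyping, scope_interpretation, modality,
  fee_eur, offered_years`; semicolons separate inner lists, flags are 0/1,
  an empty `offered_years` means always offered.
* `center.yaml` — `center_id`, `techniques` (id, validation date, method
  class `in_house`/`ce_kit`, annual volume, optional last method change,
  exemption-documentation flag) and `indications` (name, techniques used,
  annual requests).
* `history.csv` — `center_id, scheme_id, year, outcome, capa_documented`
  with outcomes `satisfactory`, `clerical_error`, `analytical_error`,
  `genotyping_error`, `critical_interpretation_error`.

Money is stored as integer euro cents throughout; sums are exact.

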