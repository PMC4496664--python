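# agestage

Age-stage, two-sex life table analysis for cohort rearing studies.

Entomologists and pest-management researchers rear a cohort of insects from
egg to death, recording each individual's developmental stage and egg
production every day. This package turns those daily records into the full
demographic toolkit of the age-stage, two-sex life table: unlike classical
female-only, age-classified life tables, it keeps track of both sexes and of
the variable developmental rates among individuals, so an individual's state
is the pair (age *x* in days, stage *j*).

## What it computes

From a cohort of *N* eggs:

- **Schedules** — the age-stage survival rate *s<sub>xj</sub>* (probability a
  newborn is alive in stage *j* at age *x*), the age-specific survival rate
  *l<sub>x</sub>* = Σ<sub>j</sub> *s<sub>xj</sub>*, the age-stage fecundity
  *f<sub>xj</sub>*, the pooled age-specific fecundity
  *m<sub>x</sub>* = Σ<sub>j</sub> *s<sub>xj</sub>f<sub>xj</sub>* / Σ<sub>j</sub> *s<sub>xj</sub>*,
  and the net maternity φ<sub>x</sub> = *l<sub>x</sub>m<sub>x</sub>*.
- **Population parameters** — the net reproductive rate
  *R*₀ = Σ<sub>x</sub> *l<sub>x</sub>m<sub>x</sub>*; the intrinsic rate of
  increase *r* solving the Euler–Lotka equation
  Σ<sub>x</sub> e<sup>−r(x+1)</sup>*l<sub>x</sub>m<sub>x</sub>* = 1 by
  bisection (age indexed from 0, end-of-day birth pulse); the finite rate
  λ = e<sup>r</sup>; and the mean generation time *T* = ln *R*₀ / *r*.
  The exact identity *R*₀ = *F*·*N*<sub>f</sub>/*N* (mean female fecundity
  times the fraction of eggs becoming females) is asserted on every cohort.
- **Matrices** — life expectancy *e<sub>xj</sub>* and reproductive value
  *v<sub>xj</sub>* for every observed age-stage cell; *e*₀₁ equals the
  cohort's mean longevity and *v*₀₁ equals λ, both exactly.
- **Timing statistics** — APOP (adult pre-oviposition period), TPOP (total
  pre-oviposition period), oviposition days, per-sex adult longevity and
  per-stage developmental durations.
- **Uncertainty** — bootstrap SEs (resampling individuals with replacement)
  for every statistic, and a paired bootstrap test comparing two cohorts via
  the percentile CI of the difference distribution.
- **Projection** — deterministic stage-structured population projection from
  the schedules, with generation tracking and a trailing growth-rate
  estimator that converges to λ.

A calibrated synthetic-cohort generator (presets for the sweetpotato weevil
*Cylas formicarius* reared on its major host *Ipomoea batatas* and the
alternative host *I. triloba*) makes the whole pipeline runnable and testable
without any external data.

## Worked example

```python
from agestage import (simulate_cohort, table1_presets, demographic_params,
                      bootstrap_cohort, paired_bootstrap_compare)

cohort = simulate_cohort(table1_presets("batatas"), n=150, seed=42)
params = demographic_params(cohort)
print(f"R0     = {params.R0:.2f} offspring/individual")
print(f"r      = {params.r:.4f} per day")
print(f"lambda = {params.lam:.4f} per day")
print(f"T      = {params.T:.2f} days")

boot = bootstrap_cohort(cohort, B=2000, seed=1, statistics=["R0", "r"])
print(f"bootstrap SE: R0 {boot.se['R0']:.2f}, r {boot.se['r']:.4f}")

other = simulate_cohort(table1_presets("triloba"), n=150, seed=43)
res = paired_bootstrap_compare(cohort, other, B=2000, seed=2, statistics=["r"])
row = res.table.loc["r"]
print(f"r difference = {row['diff']:.4f}, 95% CI [{row['ci_low']:.4f}, "
      f"{row['ci_high']:.4f}], P = {row['p']:.4f}")
```

prints

```
R0     = 56.86 offspring/individual
r      = 0.0607 per day
lambda = 1.0625 per day
T      = 66.60 days
bootstrap SE: R0 3.55, r 0.0011
r difference = 0.0226, 95% CI [0.0198, 0.0257], P = 0.0010
```

Read: each initial egg of this cohort leaves ~57 offspring; the population
grows ~6.2% per day, multiplying *R*₀-fold every ~67 days. The paired
bootstrap puts the daily growth advantage on the major host at ~0.023 d⁻¹,
significantly above zero (the p-value floor at B = 2000 is 2/(B+1) ≈ 0.001).

The same pipeline is available from the shell:

```sh
agestage simulate --preset batatas --n 150 --seed 42 --out cohort.csv
agestage analyze  --input cohort.csv --bootstrap 2000 --seed 1 --out-dir results/
agestage compare  --input a.csv --input-b b.csv --out-dir results/
agestage project  --input cohort.csv --initial-eggs 150 --horizon 180 --out-dir results/
```

Cohort files are long-format CSV (`id,age,stage,eggs`, one row per
individual per day of age); stage schemas are small YAML files listing the
ordered stages, the reproductive stages and the sex branch point.

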