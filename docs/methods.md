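# Methods

## The age-stage, two-sex life table

The analysis follows the age-stage, two-sex framework of insect demography:
every individual of a reared cohort is followed daily from oviposition to
death, and its state is the pair (age *x* in days, developmental stage *j*).
Because stage is tracked alongside age, the framework captures both sexes
and the spread of developmental rates among individuals — the overlap of
stage curves that a female-only, age-classified table cannot represent.

All estimates are nonparametric empirical summaries of the raw records; no
smoothing or parametric fitting is applied anywhere.

### Census and timing conventions

These conventions are used consistently across every quantity; the second
one is the linchpin that makes the internal identities exact.

- **Daily census.** Age 0 is the day of oviposition. An individual
  contributes to *s<sub>xj</sub>* iff it is alive and in stage *j* at the
  age-*x* census; the last day present in its record is its last day alive.
- **End-of-day birth pulse.** Eggs laid during an age-*x* day are discounted
  by e<sup>−r(x+1)</sup> in the Euler–Lotka equation, valued the same way in
  *v<sub>xj</sub>*, and enter the projection as age-0 newborns the next day.
  With this single convention: the projection's asymptotic daily growth
  equals λ = e<sup>r</sup>, the reproductive value at birth equals λ, and the
  life expectancy at birth equals the cohort mean longevity — all to
  numerical precision, and all verified by the test suite on every cohort.
- **Stage durations** count census days spent in the stage. Individuals
  dying inside a non-terminal stage never completed it and are excluded from
  that stage's duration mean; terminal (adult) stages count every entrant,
  so the adult-stage "duration" is adult longevity. The female count
  *N*<sub>f</sub> includes females that laid no eggs — the convention under
  which *R*₀ = *F*·*N*<sub>f</sub>/*N* is an exact identity (asserted at
  1e−12·*N* on every analysed cohort as an error check).
- **APOP/TPOP** are computed over females that laid at least one egg;
  fecundity *F* averages over all emerged females.

### Estimators

- *s<sub>xj</sub>* = (count alive in stage *j* at age *x*)/*N*;
  *l<sub>x</sub>* = Σ<sub>j</sub> *s<sub>xj</sub>*.
- *f<sub>xj</sub>* = mean eggs over the individuals alive in cell (*x*, *j*)
  — not over all females — so that φ<sub>x</sub> = Σ<sub>j</sub>
  *s<sub>xj</sub>f<sub>xj</sub>* equals the cohort's realised egg output per
  initial individual and φ = *l·m* holds wherever *l* > 0. Ages with
  *l<sub>x</sub>* = 0 report *m<sub>x</sub>* as missing and φ<sub>x</sub> = 0.
- **Euler–Lotka solver**: bisection on the decreasing residual
  Σ e<sup>−r(x+1)</sup>φ<sub>x</sub> − 1, starting from the bracket
  [−1, max(1, ln *R*₀ + 1)] (the upper end is provably past the root since
  the residual is negative once r > ln *R*₀; the lower end is doubled until
  the residual is positive). Iterations stop when |residual| < 1e−12, with
  a 200-iteration cap; the solver is vectorised so each bootstrap resample
  costs one row of the batch. Degenerate inputs: *R*₀ = 0 has no root and
  raises (or is recorded missing inside the bootstrap); |r| < 1e−10 makes
  *T* = ln *R*₀/r a 0/0 form, replaced by its limit
  Σ (x+1)φ<sub>x</sub>/R₀, the cohort generation time.
- **Life expectancy and reproductive value** are computed by a backward
  dynamic-programming pass over the empirical daily transition matrices
  *P<sub>i</sub>*[y, z] (fraction of cell (i, y) occupants alive in stage z
  the next day): e<sub>i</sub> = 1 + *P<sub>i</sub>*·e<sub>i+1</sub> and the
  discounted maternity accumulator for *v*. This is algebraically identical
  to summing the forward-propagated conditional survival s′ (exposed as
  `conditional_survival`), and the two routes are cross-checked in the
  tests. Cells never observed (s<sub>xj</sub> = 0) are reported missing, not
  zero.

## Bootstrap inference

Each resample redraws *N* individuals with replacement (a multinomial weight
vector) and recomputes every statistic. The reported SE is the standard
deviation of the resample estimates. Resamples with no reproduction record
*R*₀ = 0 and leave r, λ and *T* missing; they are excluded from those
summaries but counted and reported, since the Euler–Lotka equation is
unsolvable there.

Two cohorts are compared with the paired bootstrap test: B resamples of
each cohort are drawn from independent streams spawned from one seed, paired
by resample index, and the difference distribution provides a percentile CI
and the two-sided p-value
p = min(1, 2·min((#{d ≤ 0}+1), (#{d ≥ 0}+1))/(B+1)). The +1 correction
keeps p above its floor 2/(B+1) — a bootstrap can never certify p = 0. A
statistic undefined in more than half of the resample pairs is reported
missing with the dropped count. Percentile intervals only; BCa or
studentised intervals are out of scope. The default B for interactive CLI
runs is 2,000 (a desk-scale default; field studies of this kind commonly use
40,000, which remains available via `--bootstrap`).

## Population projection

The projection iterates the expected-value renewal dynamics implied by the
schedules: b(0) eggs are placed at day 0 and
b(t) = Σ<sub>x</sub> φ<sub>x</sub> b(t−x−1) thereafter; stage abundances are
the convolution of the birth series with the *s<sub>xj</sub>* columns. A
newborn's generation is its parent's plus one, and the per-generation birth
series sum exactly to the totals (linearity). No demographic stochasticity
is simulated. The default horizon is 180 days, configurable. The trailing
geometric-mean growth estimator converges to λ at the 1e−3 level after a few
hundred days on the cohorts tested, limited by the geometric decay of the
initial-pulse transient.

## Synthetic cohorts

Raw per-individual records for the motivating host-plant comparison (the
sweetpotato weevil on *Ipomoea batatas* vs *I. triloba*) are not publicly
deposited, so the generator emulates cohorts whose summary statistics are
calibrated to the published per-host means: stage-duration means and SEs,
per-stage completion probabilities (149/150, 146/149, 1.0 on batatas; all
1.0 on triloba, as printed), sex ratio at emergence (90/146 and 83/150),
mean APOP, lifetime fecundity, oviposition-day count, adult longevities, and
N = 150 eggs per cohort.

Choices where the published summaries underdetermine the model:

- **Durations** are gamma variates matched to (mean, SD) with SD = SE·√n,
  rounded to whole days after a 1-day shift (minimum 1 day, mean preserved
  under discretisation). A gamma is the natural positive, right-skewed
  two-moment family for development times.
- **APOP** is Poisson with the published mean (0.10/0.07 d) — the simplest
  count distribution on {0, 1, …} with roughly the right spread.
- **Laying days** are a uniform random subset of the first ~40 days of
  adult life (42 d on batatas, 39 d on triloba), the first falling APOP days
  after emergence; total fecundity is spread one-egg-minimum-plus-multinomial
  across them. The window is calibrated to the published reproductive-value
  curves, which show reproduction ceasing roughly 40 days after female
  emergence on both hosts; without the window, spreading ~30 laying days
  over an ~88-day adult life would push the maternity schedule far too late
  and bias r down by ~15%.
- **Mortality placement**: an individual failing a stage dies at a uniformly
  chosen day within its sampled stage duration.
- Fecundity and longevity are drawn **independently**; the published
  summaries give no covariance. Real cohorts likely correlate the two, so
  the synthetic r is a slightly smoothed version of reality — a known
  fidelity limit.

What passing tests therefore show: the pipeline recovers the generating
means (stage durations, F, TPOP) within 3 SEs in ≥95% of seeds, reproduces
every qualitative host ordering (r, λ, R₀ higher and T lower on the major
host, APOP not distinguishable) with the paired test, and the test's type-I
error at α = 0.05 is nominal within binomial error over 200 replicate
pairs. What they do not show: agreement of the synthetic cohorts' r/λ/T
point values with any particular real cohort — daily laying schedules and
trait covariances of real weevils are not in the generator.

## Problem sizes used by the test and acceptance runs

Cohorts of n = 150 (the study design size); bootstrap B = 2,000 for SEs and
comparisons, B = 10⁵ for the exhaustive-enumeration Monte-Carlo check at
n = 2; 100 seeds for parameter recovery; 200 replicate pairs at B = 1,000
for the type-I calibration; projection horizons of 180 d (reporting) and
300–900 d (growth-rate convergence checks). All are the package's own
defaults for a reproducible desk-scale analysis.

## Known limitations

- The generator emulates summary statistics, not trajectories: real daily
  fecundity schedules (early peak, long tail) and duration/fecundity
  covariances are not reproduced.
- Percentile bootstrap CIs can be mildly anticonservative at n = 150 for
  highly skewed statistics; the type-I calibration test bounds this.
- The projection is deterministic; extinction risk at small inocula needs a
  stochastic branching model, which is out of scope.
- Stage schemas support one sex branch at a single branch point; more
  complex polymorphisms (e.g. wing morphs) would need a schema extension.
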