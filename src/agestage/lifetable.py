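"""Age-stage, two-sex life table: schedules and demographic parameters.

The framework keeps track of each individual's state as (age x in days,
developmental stage j), so survivorship and fecundity are matrices rather
than vectors and both sexes contribute to the table.  All estimates are
nonparametric empirical summaries of the daily cohort records: no smoothing
or parametric fitting anywhere.

Core quantities
---------------
s_xj   probability a newborn is alive and in stage j at age x
l_x    age-specific survival rate, sum over stages of s_xj
f_xj   mean daily eggs of the individuals alive in (x, j)
m_x    age-specific fecundity, (sum_j s_xj f_xj) / (sum_j s_xj)
phi_x  net maternity l_x * m_x = sum_j s_xj f_xj
R0     net reproductive rate, sum_x phi_x
r      intrinsic rate of increase, root of sum_x exp(-r (x+1)) phi_x = 1
lambda finite rate of increase, exp(r)
T      mean generation time, ln(R0) / r
e_xj   life expectancy at (x, j)
v_xj   reproductive value at (x, j); v at birth equals lambda

The Euler-Lotka exponent uses (x + 1): births during the age-x day are
censused at the end of that day.  Life expectancy and reproductive value use
the same end-of-day convention, which is what makes v at age 0 equal lambda
exactly and projection growth equal exp(r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError, cohort_counts

__all__ = [
    "SurvivalSchedule",
    "FecunditySchedule",
    "DemographicParams",
    "ConditionalSurvival",
    "ExpectancyMatrix",
    "ReproValueMatrix",
    "ReproductionStats",
    "compute_survival_schedule",
    "compute_fecundity_schedules",
    "net_reproductive_rate",
    "solve_intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "conditional_survival",
    "life_expectancy",
    "reproductive_value",
    "reproduction_stats",
    "stage_duration_stats",
    "r0_consistency",
    "demographic_params",
]


# ---------------------------------------------------------------------------
# occupancy arrays


def _occupancy(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Dense (n, A+1) arrays: stage index occupied (-1 once dead) and eggs."""
    if cohort.n == 0:
        raise CohortError("empty cohort")
    A = cohort.max_age
    n = cohort.n
    stage_idx = np.full((n, A + 1), -1, dtype=np.int64)
    eggs = np.zeros((n, A + 1), dtype=np.float64)
    for i, rec in enumerate(cohort.records):
        for age, (stage, e) in enumerate(rec.days):
            stage_idx[i, age] = cohort.schema.index(stage)
            eggs[i, age] = e
    return stage_idx, eggs


# ---------------------------------------------------------------------------
# schedules


@dataclass
class SurvivalSchedule:
    """Age-stage survival matrix s (A+1 x m) and its row sum l."""

    s: np.ndarray
    l: np.ndarray
    stages: tuple[str, ...]

    @property
    def max_age(self) -> int:
        return self.s.shape[0] - 1


@dataclass
class FecunditySchedule:
    """Age-stage fecundity f (A+1 x m), pooled m_x (NaN where l_x = 0), phi."""

    f: np.ndarray
    m_x: np.ndarray
    phi: np.ndarray
    stages: tuple[str, ...]


@dataclass
class DemographicParams:
    """Population parameters with the F, N_f, N bookkeeping behind R0."""

    R0: float
    r: float
    lam: float
    T: float
    F: float
    n_female: int
    n_male: int
    n: int


def compute_survival_schedule(cohort: Cohort) -> SurvivalSchedule:
    """s_xj = (number alive in stage j at the age-x census) / N."""
    stage_idx, _ = _occupancy(cohort)
    m = cohort.schema.m
    A = stage_idx.shape[1] - 1
    s = np.zeros((A + 1, m))
    for j in range(m):
        s[:, j] = (stage_idx == j).sum(axis=0) / cohort.n
    return SurvivalSchedule(s=s, l=s.sum(axis=1), stages=cohort.schema.stages)


def compute_fecundity_schedules(
    cohort: Cohort, surv: SurvivalSchedule
) -> FecunditySchedule:
    """f_xj averaged over occupants of (x, j); m_x = phi_x / l_x.

    The f_xj denominator is the count of individuals alive in that age-stage
    cell (not all females), so that s_xj * f_xj recovers the cohort's total
    egg output per initial individual and phi_x = l_x * m_x holds exactly.
    Ages with l_x = 0 have m_x reported as NaN and phi_x = 0.
    """
    stage_idx, eggs = _occupancy(cohort)
    A = stage_idx.shape[1] - 1
    if surv.s.shape[0] != A + 1:
        raise ValueError("survival schedule does not match cohort ages")
    m = cohort.schema.m
    f = np.zeros((A + 1, m))
    for j in range(m):
        occ = stage_idx == j
        cnt = occ.sum(axis=0)
        tot = np.where(occ, eggs, 0.0).sum(axis=0)
        np.divide(tot, cnt, out=f[:, j], where=cnt > 0)
    phi = eggs.sum(axis=0) / cohort.n
    m_x = np.full(A + 1, np.nan)
    np.divide(phi, surv.l, out=m_x, where=surv.l > 0)
    return FecunditySchedule(f=f, m_x=m_x, phi=phi, stages=cohort.schema.stages)


def net_reproductive_rate(fec: FecunditySchedule) -> float:
    """R0 = sum_x phi_x = sum_x l_x m_x (expected offspring per initial egg)."""
    return float(fec.phi.sum())


# ---------------------------------------------------------------------------
# Euler-Lotka


def _euler_lotka_batch(
    phi: np.ndarray, tol: float = 1e-12, max_iter: int = 200
) -> np.ndarray:
    """Vectorised bisection for sum_x exp(-r (x+1)) phi_x = 1, rows of ``phi``.

    Rows with zero total reproduction get NaN.  The bracket starts at
    [-1, max(1, ln R0 + 1)] — the upper end is guaranteed past the root
    because the residual is below zero once r > ln R0 — and the lower end is
    doubled until the residual is positive there.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if not np.isfinite(phi).all():
        raise ValueError("non-finite net maternity values")
    B, width = phi.shape
    ages1 = np.arange(1, width + 1, dtype=float)
    R0 = phi.sum(axis=1)
    solvable = R0 > 0

    def residual(r: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return (np.exp(-r[:, None] * ages1[None, :]) * phi).sum(axis=1) - 1.0

    lo = np.full(B, -1.0)
    hi = np.maximum(1.0, np.log(np.where(solvable, R0, 1.0)) + 1.0)
    for _ in range(64):
        bad = solvable & (residual(lo) <= 0)
        if not bad.any():
            break
        lo[bad] *= 2.0
    root = np.full(B, np.nan)
    active = solvable.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        mid = 0.5 * (lo + hi)
        res = residual(mid)
        pos = res > 0
        lo = np.where(active & pos, mid, lo)
        hi = np.where(active & ~pos, mid, hi)
        done = active & (np.abs(res) < tol)
        root[done] = mid[done]
        active &= ~done
    if active.any():  # residual floor reached; take the bracket midpoint
        mid = 0.5 * (lo + hi)
        root[active] = mid[active]
    return root


def solve_intrinsic_rate(fec: FecunditySchedule, tol: float = 1e-12) -> float:
    """Solve the Euler-Lotka equation for r by iterative bisection.

    Raises if the cohort has no reproduction (R0 = 0, no finite root) or the
    schedule contains non-finite values.
    """
    if not np.isfinite(fec.phi).all():
        raise ValueError("non-finite net maternity values")
    if fec.phi.sum() <= 0:
        raise ValueError("R0 = 0: intrinsic rate has no solution")
    return float(_euler_lotka_batch(fec.phi[None, :], tol=tol)[0])


def finite_rate(r: float) -> float:
    """Finite (daily) rate of increase lambda = exp(r)."""
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    return float(np.exp(r))


def mean_generation_time(
    R0: float, r: float, phi: np.ndarray | None = None
) -> float:
    """T = ln(R0) / r, the time for an R0-fold increase at the stable
    age-stage distribution.

    For |r| < 1e-10 the ratio is 0/0; the limit is the cohort generation
    time sum_x (x+1) phi_x / R0, which requires the ``phi`` schedule.
    """
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if abs(r) < 1e-10:
        if phi is None:
            raise ValueError("r ~ 0: supply phi to compute the limit")
        phi = np.asarray(phi, dtype=float)
        return float((np.arange(1, phi.size + 1) * phi).sum() / R0)
    return float(np.log(R0) / r)


def r0_consistency(F: float, n_female: int, n: int) -> float:
    """The exact identity R0 = F * (N_f / N).

    F is the mean lifetime fecundity over all emerged females (zero layers
    included); the pipeline asserts agreement with the schedule summation on
    every cohort as an internal error check.
    """
    if n <= 0:
        raise ValueError("N must be positive")
    if not 0 <= n_female <= n:
        raise ValueError("need 0 <= N_f <= N")
    return float(F) * n_female / n


# ---------------------------------------------------------------------------
# conditional survival, life expectancy, reproductive value


@dataclass
class ConditionalSurvival:
    """s'_iy: survival of an individual known alive at the origin (x, j).

    ``s_prime`` has the same shape as the survival matrix; rows before the
    origin age are zero and s'_xj = 1 at the origin.
    """

    origin: tuple[int, int]
    s_prime: np.ndarray
    stages: tuple[str, ...]


def _transition_fractions(cohort: Cohort) -> tuple[np.ndarray, list[np.ndarray]]:
    """Occupancy counts o (A+1, m) and per-day transition matrices P_i.

    P_i[y, z] is the empirical fraction of the individuals alive in stage y
    at age i that are alive in stage z at age i+1 (the missing row mass
    died overnight).  Rows with no occupants are zero.
    """
    stage_idx, _ = _occupancy(cohort)
    m = cohort.schema.m
    A = stage_idx.shape[1] - 1
    occ = np.zeros((A + 1, m))
    for j in range(m):
        occ[:, j] = (stage_idx == j).sum(axis=0)
    P: list[np.ndarray] = []
    for i in range(A):
        cnt = np.zeros((m, m))
        frm = stage_idx[:, i]
        to = stage_idx[:, i + 1]
        alive = (frm >= 0) & (to >= 0)
        np.add.at(cnt, (frm[alive], to[alive]), 1.0)
        with np.errstate(invalid="ignore"):
            frac = cnt / occ[i][:, None]
        frac[occ[i] == 0] = 0.0
        P.append(frac)
    return occ, P


def conditional_survival(
    cohort: Cohort, x: int, j: int | str
) -> ConditionalSurvival:
    """Propagate s' forward from (x, j) using empirical daily transitions."""
    if isinstance(j, str):
        j = cohort.schema.index(j)
    occ, P = _transition_fractions(cohort)
    A = occ.shape[0] - 1
    m = occ.shape[1]
    if not (0 <= x <= A and 0 <= j < m) or occ[x, j] == 0:
        raise CohortError(f"no individuals observed at age {x}, stage index {j}")
    s_prime = np.zeros((A + 1, m))
    s_prime[x, j] = 1.0
    for i in range(x, A):
        s_prime[i + 1] = s_prime[i] @ P[i]
    return ConditionalSurvival(origin=(x, j), s_prime=s_prime, stages=cohort.schema.stages)


@dataclass
class ExpectancyMatrix:
    """e_xj: expected further days of life at (x, j); NaN where s_xj = 0."""

    e: np.ndarray
    stages: tuple[str, ...]


@dataclass
class ReproValueMatrix:
    """v_xj: discounted expected future births per individual at (x, j);
    NaN where s_xj = 0."""

    v: np.ndarray
    stages: tuple[str, ...]


def life_expectancy(cohort: Cohort) -> ExpectancyMatrix:
    """e_xj = sum over i >= x and all stages of s'_iy from origin (x, j).

    Computed by one backward dynamic-programming pass over the daily
    transition matrices: an individual alive today lives today (the +1) plus
    the expectation carried by each stage it may occupy tomorrow.  The
    expectancy at age 0 in the first stage equals the cohort mean days alive.
    """
    occ, P = _transition_fractions(cohort)
    A = occ.shape[0] - 1
    e = np.full_like(occ, np.nan)
    nxt = np.ones(occ.shape[1])
    e[A] = np.where(occ[A] > 0, 1.0, np.nan)
    for i in range(A - 1, -1, -1):
        vals = 1.0 + P[i] @ np.nan_to_num(np.where(occ[i + 1] > 0, e[i + 1], 0.0))
        e[i] = np.where(occ[i] > 0, vals, np.nan)
    return ExpectancyMatrix(e=e, stages=cohort.schema.stages)


def reproductive_value(
    cohort: Cohort, fec: FecunditySchedule, r: float
) -> ReproValueMatrix:
    """v_xj per the age-stage framework: exp(r (x+1)) times the sum over
    future ages i of exp(-r (i+1)) times the conditional expected eggs laid
    at age i, conditioning on being alive at (x, j).

    The same backward recursion as the life expectancy, with end-of-day
    discounting; v at age 0 in the first stage equals lambda exactly when r
    solves the Euler-Lotka equation on the same cohort.
    """
    occ, P = _transition_fractions(cohort)
    A = occ.shape[0] - 1
    if fec.f.shape != occ.shape:
        raise ValueError("fecundity schedule does not match cohort")
    # W_i(y) = sum_{i' >= i} exp(-r (i'+1)) * E[eggs at (i', y') | alive (i, y)]
    W = np.zeros_like(occ)
    W[A] = np.exp(-r * (A + 1)) * fec.f[A]
    for i in range(A - 1, -1, -1):
        W[i] = np.exp(-r * (i + 1)) * fec.f[i] + P[i] @ W[i + 1]
    with np.errstate(over="ignore"):
        v = np.exp(r * (np.arange(A + 1) + 1.0))[:, None] * W
    v[occ == 0] = np.nan
    return ReproValueMatrix(v=v, stages=cohort.schema.stages)


# ---------------------------------------------------------------------------
# per-individual reproduction and duration statistics


@dataclass
class ReproductionStats:
    """Per-female reproduction timing and per-sex adult longevity.

    ``females`` has one row per emerged female: emergence age, first-egg age
    (NaN if she laid nothing), APOP, TPOP, oviposition days and lifetime
    fecundity.  APOP/TPOP means cover only females that laid at least one
    egg; the fecundity mean F covers all emerged females, which is the
    convention under which R0 = F * N_f / N holds exactly.
    """

    females: pd.DataFrame
    F: float
    apop_mean: float
    tpop_mean: float
    oviposition_days_mean: float
    female_longevity_mean: float
    male_longevity_mean: float
    n_female: int
    n_male: int

    @property
    def n_laying(self) -> int:
        return int(self.females["first_egg_age"].notna().sum())


def _adult_stages(cohort: Cohort) -> tuple[set[str], set[str]]:
    schema = cohort.schema
    branch = set(schema.branch_stages)
    repro = set(schema.reproductive_stages)
    if branch:
        return branch & repro or repro, branch - repro
    return repro, set()


def reproduction_stats(cohort: Cohort) -> ReproductionStats:
    """APOP, TPOP, oviposition days, fecundity and adult longevities."""
    female_stages, male_stages = _adult_stages(cohort)
    rows = []
    male_longevities = []
    for rec in cohort.records:
        stages = [s for s, _ in rec.days]
        f_days = [a for a, s in enumerate(stages) if s in female_stages]
        m_days = [a for a, s in enumerate(stages) if s in male_stages]
        if m_days:
            male_longevities.append(len(m_days))
        if not f_days:
            continue
        emergence = f_days[0]
        egg_ages = [a for a, (_, e) in enumerate(rec.days) if e > 0]
        first = egg_ages[0] if egg_ages else np.nan
        rows.append(
            {
                "id": rec.id,
                "emergence_age": emergence,
                "first_egg_age": first,
                "apop": first - emergence if egg_ages else np.nan,
                "tpop": first,
                "oviposition_days": len(egg_ages),
                "fecundity": sum(e for _, e in rec.days),
                "adult_longevity": len(f_days),
            }
        )
    females = pd.DataFrame(
        rows,
        columns=[
            "id",
            "emergence_age",
            "first_egg_age",
            "apop",
            "tpop",
            "oviposition_days",
            "fecundity",
            "adult_longevity",
        ],
    )
    def _mean(series: pd.Series) -> float:
        return float(series.mean()) if len(series) and series.notna().any() else float("nan")

    return ReproductionStats(
        females=females,
        F=_mean(females["fecundity"]),
        apop_mean=_mean(females["apop"]),
        tpop_mean=_mean(females["tpop"].where(females["first_egg_age"].notna())),
        oviposition_days_mean=_mean(females["oviposition_days"]),
        female_longevity_mean=_mean(females["adult_longevity"]),
        male_longevity_mean=(
            float(np.mean(male_longevities)) if male_longevities else float("nan")
        ),
        n_female=len(females),
        n_male=len(male_longevities),
    )


def stage_duration_stats(cohort: Cohort) -> pd.DataFrame:
    """Mean stage durations over completers only.

    Individuals dying inside a non-terminal stage never completed it and are
    excluded from that stage's mean; terminal (adult) stages count every
    entrant, with duration equal to adult longevity.  Returns a DataFrame
    indexed by stage with columns ``n``, ``mean``, ``sd``.
    """
    schema = cohort.schema
    branch = set(schema.branch_stages)
    terminal = branch if branch else {schema.stages[-1]}
    durations: dict[str, list[int]] = {s: [] for s in schema.stages}
    for rec in cohort.records:
        runs: list[tuple[str, int]] = []
        for stage, _ in rec.days:
            if runs and runs[-1][0] == stage:
                runs[-1] = (stage, runs[-1][1] + 1)
            else:
                runs.append((stage, 1))
        for i, (stage, d) in enumerate(runs):
            if stage in terminal or i < len(runs) - 1:
                durations[stage].append(d)
    rows = []
    for stage in schema.stages:
        d = np.asarray(durations[stage], dtype=float)
        rows.append(
            {
                "stage": stage,
                "n": d.size,
                "mean": d.mean() if d.size else np.nan,
                "sd": d.std(ddof=1) if d.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("stage")


# ---------------------------------------------------------------------------
# one-call summary


def demographic_params(cohort: Cohort, tol: float = 1e-12) -> DemographicParams:
    """R0, r, lambda, T plus the F / N_f / N bookkeeping, in one call.

    A cohort with no reproduction gets R0 = 0 and NaN for r, lambda and T.
    The R0 = F * N_f / N identity is asserted (to 1e-12 * N) as a guard
    against bookkeeping errors.
    """
    surv = compute_survival_schedule(cohort)
    fec = compute_fecundity_schedules(cohort, surv)
    R0 = net_reproductive_rate(fec)
    counts = cohort_counts(cohort)
    repro = reproduction_stats(cohort)
    n_f = counts.n_female
    if n_f > 0:
        check = r0_consistency(repro.F, n_f, cohort.n)
        if abs(check - R0) > 1e-12 * cohort.n:
            raise AssertionError(
                f"R0 bookkeeping mismatch: schedules give {R0}, F*Nf/N gives {check}"
            )
    if R0 > 0:
        r = solve_intrinsic_rate(fec, tol=tol)
        lam = finite_rate(r)
        T = mean_generation_time(R0, r, phi=fec.phi)
    else:
        r = lam = T = float("nan")
    return DemographicParams(
        R0=R0,
        r=r,
        lam=lam,
        T=T,
        F=repro.F,
        n_female=n_f,
        n_male=counts.n_male,
        n=cohort.n,
    )
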