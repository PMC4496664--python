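"""Deterministic stage-structured population projection with generations.

The projection iterates the expected-value dynamics implied by the cohort's
age-stage schedules: a pulse of newborn eggs is placed at day 0, each day
the existing birth cohorts age one day, and the eggs laid during the age-x
day of a birth cohort enter the population as age-0 newborns the following
day.  That end-of-day timing is the same (x + 1) convention used in the
Euler-Lotka equation, which is what makes the long-run projection growth
rate equal lambda = exp(r) from the life table on the same cohort.

No demographic stochasticity is simulated; abundances are expected values
and may be fractional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .lifetable import compute_fecundity_schedules, compute_survival_schedule

__all__ = [
    "ProjectionSchedules",
    "ProjectionResult",
    "build_projection_schedules",
    "project_population",
    "estimate_growth_rate",
]


@dataclass
class ProjectionSchedules:
    """Per-newborn expected stage occupancy s_xj and daily egg output phi_x."""

    s: np.ndarray  # (A+1, m)
    phi: np.ndarray  # (A+1,)
    stages: tuple[str, ...]

    @property
    def max_age(self) -> int:
        return self.s.shape[0] - 1

    def to_csv(self, path: str | Path) -> None:
        """Long CSV ``age,stage,s,phi`` (phi repeated across stages of an age)."""
        A1, m = self.s.shape
        df = pd.DataFrame(
            {
                "age": np.repeat(np.arange(A1), m),
                "stage": list(self.stages) * A1,
                "s": self.s.ravel(),
                "phi": np.repeat(self.phi, m),
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProjectionSchedules":
        df = pd.read_csv(path)
        stages = tuple(dict.fromkeys(df["stage"]))
        ages = np.sort(df["age"].unique())
        A1, m = ages.size, len(stages)
        s = np.zeros((A1, m))
        phi = np.zeros(A1)
        for j, stage in enumerate(stages):
            sub = df[df["stage"] == stage].sort_values("age")
            s[:, j] = sub["s"].to_numpy()
            phi = sub["phi"].to_numpy()
        return cls(s=s, phi=phi, stages=stages)


@dataclass
class ProjectionResult:
    """Day-by-day birth and abundance series, decomposed by generation."""

    births: np.ndarray  # (H+1,) newborns entering at each day
    stage_counts: np.ndarray  # (H+1, m) abundance per stage
    totals: np.ndarray  # (H+1,)
    births_by_generation: np.ndarray  # (G, H+1), rows sum to births
    stages: tuple[str, ...]

    @property
    def horizon(self) -> int:
        return self.births.size - 1

    @property
    def n_generations(self) -> int:
        return self.births_by_generation.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long DataFrame ``day,generation,stage,count`` plus a per-day total."""
        H1 = self.births.size
        m = len(self.stages)
        G = self.n_generations
        # stage occupancy of generation g at day t: convolve its birth series
        rows = []
        for g in range(G):
            bg = self.births_by_generation[g]
            for j, stage in enumerate(self.stages):
                col = np.convolve(bg, self._s_col[:, j])[:H1]
                rows.append(
                    pd.DataFrame(
                        {
                            "day": np.arange(H1),
                            "generation": g,
                            "stage": stage,
                            "count": col,
                        }
                    )
                )
        df = pd.concat(rows, ignore_index=True)
        totals = pd.Series(self.totals, name="total")
        df = df.merge(
            totals.rename_axis("day").reset_index(), on="day", how="left"
        )
        return df

    # survival columns stashed by project_population for the long export
    _s_col: np.ndarray = None  # type: ignore[assignment]


def build_projection_schedules(cohort: Cohort) -> ProjectionSchedules:
    """Schedules for projection, identical to the life table outputs."""
    surv = compute_survival_schedule(cohort)
    fec = compute_fecundity_schedules(cohort, surv)
    phi = np.where(surv.l > 0, fec.phi, 0.0)
    return ProjectionSchedules(s=surv.s, phi=phi, stages=surv.stages)


def project_population(
    sched: ProjectionSchedules, initial_eggs: float, horizon: int
) -> ProjectionResult:
    """Project abundance from a day-0 pulse of ``initial_eggs`` newborns.

    Birth dynamics: b(0) = initial_eggs and, for t >= 1,
    b(t) = sum_x phi_x b(t - x - 1) — eggs laid during the age-x day enter
    as age-0 newborns the next day.  Stage abundances are the convolution of
    the birth series with the s_xj columns.  A newborn's generation is its
    parent's generation plus one (the inoculum is generation 0), and the
    per-generation birth series sum to b(t) exactly.
    """
    if initial_eggs < 0 or horizon < 0:
        raise ValueError("initial_eggs and horizon must be nonnegative")
    H = int(horizon)
    phi = np.asarray(sched.phi, dtype=float)
    A = phi.size - 1
    b = np.zeros(H + 1)
    b[0] = initial_eggs
    # total birth series first
    for t in range(1, H + 1):
        xmax = min(A, t - 1)
        b[t] = phi[: xmax + 1] @ b[t - 1 - xmax : t][::-1]
    # generation decomposition: each generation's births are the convolution
    # of the previous generation's births with the (x+1)-lagged phi kernel
    kernel = np.concatenate(([0.0], phi))  # lag x+1
    gens = []
    bg = np.zeros(H + 1)
    bg[0] = initial_eggs
    gens.append(bg)
    while True:
        nxt = np.convolve(gens[-1], kernel)[: H + 1]
        if not np.any(nxt > 0):
            break
        gens.append(nxt)
    births_by_generation = np.vstack(gens)
    stage_counts = np.zeros((H + 1, sched.s.shape[1]))
    for j in range(sched.s.shape[1]):
        stage_counts[:, j] = np.convolve(b, sched.s[:, j])[: H + 1]
    totals = stage_counts.sum(axis=1)
    result = ProjectionResult(
        births=b,
        stage_counts=stage_counts,
        totals=totals,
        births_by_generation=births_by_generation,
        stages=sched.stages,
    )
    result._s_col = sched.s
    return result


def estimate_growth_rate(result: ProjectionResult, window: int) -> float:
    """Geometric-mean daily growth of total abundance over the trailing window.

    Converges to the finite rate lambda once the age-stage distribution has
    stabilised (transients from the initial pulse decay geometrically).
    """
    if window < 1 or window > result.horizon:
        raise ValueError("window must be within the projected horizon")
    tail = result.totals[-(window + 1) :]
    if np.any(tail <= 0):
        raise ValueError("zero abundance in the trailing window")
    return float((tail[-1] / tail[0]) ** (1.0 / window))
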