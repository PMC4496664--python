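"""Bootstrap uncertainty and paired-bootstrap treatment comparison.

Each resample redraws N individuals with replacement from the cohort and
recomputes every life-history summary (stage durations, APOP, TPOP,
oviposition days, fecundity) and every population parameter (R0, r, lambda,
T) from scratch.  The reported SE is the standard deviation of the resample
estimates.  Two treatments are compared through the bootstrap distribution
of the difference, with a percentile confidence interval and a two-sided
p-value.

Resamples that contain no reproduction (no female drawn, or only zero-egg
females) leave the Euler-Lotka equation without a root: R0 = 0 is recorded,
r, lambda and T are recorded missing, and the count of such degenerate
resamples is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .lifetable import _euler_lotka_batch, _occupancy

__all__ = [
    "BootstrapResult",
    "ComparisonResult",
    "bootstrap_cohort",
    "paired_bootstrap_compare",
    "statistic_names",
]

_PARAM_STATS = ("R0", "r", "lambda", "T")


def statistic_names(cohort: Cohort) -> list[str]:
    """All statistics the bootstrap recomputes for this schema: one duration
    per stage (adult-stage durations are the adult longevities), the female
    reproduction summaries, and the four population parameters."""
    return (
        [f"{s}_duration" for s in cohort.schema.stages]
        + ["apop", "tpop", "oviposition_days", "fecundity"]
        + list(_PARAM_STATS)
    )


class _DenseCohort:
    """Per-individual arrays so a resample is just a weighted aggregation."""

    def __init__(self, cohort: Cohort):
        self.schema = cohort.schema
        self.n = cohort.n
        stage_idx, eggs = _occupancy(cohort)
        self.eggs = eggs  # (n, A+1)
        self.tot_eggs = eggs.sum(axis=1)

        schema = cohort.schema
        branch = set(schema.branch_stages)
        terminal = branch if branch else {schema.stages[-1]}
        repro = set(schema.reproductive_stages)
        female_stages = (branch & repro) if branch & repro else repro
        n = cohort.n
        scalars: dict[str, np.ndarray] = {
            name: np.full(n, np.nan)
            for name in (
                [f"{s}_duration" for s in schema.stages]
                + ["apop", "tpop", "oviposition_days", "fecundity"]
            )
        }
        for i, rec in enumerate(cohort.records):
            runs: list[tuple[str, int]] = []
            for stage, _ in rec.days:
                if runs and runs[-1][0] == stage:
                    runs[-1] = (stage, runs[-1][1] + 1)
                else:
                    runs.append((stage, 1))
            for k, (stage, d) in enumerate(runs):
                if stage in terminal or k < len(runs) - 1:
                    scalars[f"{stage}_duration"][i] = d
            stages_reached = {s for s, _ in runs}
            if stages_reached & female_stages:
                egg_ages = [a for a, (_, e) in enumerate(rec.days) if e > 0]
                scalars["fecundity"][i] = self.tot_eggs[i]
                scalars["oviposition_days"][i] = len(egg_ages)
                if egg_ages:
                    emergence = next(
                        a for a, (s, _) in enumerate(rec.days) if s in female_stages
                    )
                    scalars["tpop"][i] = egg_ages[0]
                    scalars["apop"][i] = egg_ages[0] - emergence
        self.scalars = scalars

    def resample_stats(
        self, W: np.ndarray, statistics: list[str], tol: float = 1e-12
    ) -> pd.DataFrame:
        """Statistic estimates for each row of weights ``W`` (counts per
        individual, rows summing to N)."""
        W = np.asarray(W, dtype=float)
        out: dict[str, np.ndarray] = {}
        for name in statistics:
            if name in self.scalars:
                vals = self.scalars[name]
                valid = np.isfinite(vals)
                num = W @ np.where(valid, vals, 0.0)
                den = W @ valid.astype(float)
                with np.errstate(invalid="ignore"):
                    out[name] = np.where(den > 0, num / den, np.nan)
        if any(p in statistics for p in _PARAM_STATS):
            R0 = W @ self.tot_eggs / self.n
            if any(p in statistics for p in ("r", "lambda", "T")):
                phi = (W @ self.eggs) / self.n
                r = _euler_lotka_batch(phi, tol=tol)
            else:
                r = np.full(W.shape[0], np.nan)
            if "R0" in statistics:
                out["R0"] = R0
            if "r" in statistics:
                out["r"] = r
            if "lambda" in statistics:
                out["lambda"] = np.exp(r)
            if "T" in statistics:
                with np.errstate(invalid="ignore", divide="ignore"):
                    out["T"] = np.where(
                        (R0 > 0) & np.isfinite(r), np.log(np.maximum(R0, 1e-300)) / r, np.nan
                    )
        return pd.DataFrame({k: out[k] for k in statistics if k in out})

    def degenerate_mask(self, W: np.ndarray) -> np.ndarray:
        return (np.asarray(W, dtype=float) @ self.tot_eggs) <= 0


@dataclass
class BootstrapResult:
    """Resample distributions and SEs for one cohort."""

    B: int
    seed: int
    samples: pd.DataFrame  # B rows, one column per statistic (NaN = undefined)
    point: pd.Series  # estimates on the original cohort
    mean: pd.Series
    se: pd.Series  # SD over the defined resample estimates
    degenerate_count: int


@dataclass
class ComparisonResult:
    """Paired-bootstrap comparison of two cohorts.

    ``table`` is indexed by statistic with the two point estimates, their
    difference, the percentile CI of the bootstrap difference distribution,
    the two-sided p-value and the number of resample pairs in which the
    difference was defined.  Statistics undefined in more than half the
    pairs are reported missing (NaN row) with the dropped count retained.
    """

    table: pd.DataFrame
    diffs: pd.DataFrame
    alpha: float
    B: int
    seed: int


def _resample_weights(rng: np.random.Generator, n: int, B: int) -> np.ndarray:
    return rng.multinomial(n, np.full(n, 1.0 / n), size=B)


def bootstrap_cohort(
    cohort: Cohort,
    B: int,
    seed: int,
    statistics: list[str] | None = None,
    tol: float = 1e-12,
) -> BootstrapResult:
    """Bootstrap all (or the selected) statistics of one cohort.

    Deterministic for a fixed ``(B, seed)``.  Degenerate resamples are
    excluded from the r / lambda / T summaries but counted.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    dense = _DenseCohort(cohort)
    stats = statistics if statistics is not None else statistic_names(cohort)
    rng = np.random.default_rng(seed)
    W = _resample_weights(rng, dense.n, B)
    samples = dense.resample_stats(W, stats, tol=tol)
    point = dense.resample_stats(np.ones((1, dense.n)), stats, tol=tol).iloc[0]
    def _nanstd(col: np.ndarray) -> float:
        col = col[np.isfinite(col)]
        return float(np.std(col, ddof=1)) if col.size > 1 else float("nan")

    return BootstrapResult(
        B=B,
        seed=seed,
        samples=samples,
        point=point,
        mean=pd.Series(
            {c: float(np.nanmean(samples[c])) if np.isfinite(samples[c]).any() else float("nan") for c in samples},
        ),
        se=pd.Series({c: _nanstd(samples[c].to_numpy()) for c in samples}),
        degenerate_count=int(dense.degenerate_mask(W).sum()),
    )


def paired_bootstrap_compare(
    a: Cohort,
    b: Cohort,
    B: int,
    seed: int,
    alpha: float = 0.05,
    statistics: list[str] | None = None,
    pair_by_index: bool = True,
    tol: float = 1e-12,
) -> ComparisonResult:
    """Compare two cohorts statistic by statistic via bootstrap differences.

    Each cohort is resampled B times from its own independent stream spawned
    from ``seed``; differences d_b = theta_b(a) - theta_b(b) are formed by
    resample index (or after shuffling b's resamples when
    ``pair_by_index=False`` — with independent streams the two choices are
    statistically equivalent).  The CI is the (alpha/2, 1-alpha/2)
    percentile interval of the defined differences, and the two-sided
    p-value uses the +1-corrected sign-count estimator, so its floor is
    2/(B+1).
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if a.schema.stages != b.schema.stages:
        raise ValueError("cohorts have different stage schemas")
    stats = statistics if statistics is not None else statistic_names(a)
    da, db = _DenseCohort(a), _DenseCohort(b)
    child_a, child_b, child_perm = np.random.SeedSequence(seed).spawn(3)
    Wa = _resample_weights(np.random.default_rng(child_a), da.n, B)
    Wb = _resample_weights(np.random.default_rng(child_b), db.n, B)
    sa = da.resample_stats(Wa, stats, tol=tol)
    sb = db.resample_stats(Wb, stats, tol=tol)
    if not pair_by_index:
        perm = np.random.default_rng(child_perm).permutation(B)
        sb = sb.iloc[perm].reset_index(drop=True)
    diffs = sa - sb
    point_a = da.resample_stats(np.ones((1, da.n)), stats, tol=tol).iloc[0]
    point_b = db.resample_stats(np.ones((1, db.n)), stats, tol=tol).iloc[0]
    rows = []
    for name in diffs.columns:
        d = diffs[name].to_numpy()
        valid = np.isfinite(d)
        nv = int(valid.sum())
        dropped = B - nv
        if nv < B / 2 or nv == 0:
            rows.append(
                {
                    "statistic": name,
                    "point_a": point_a[name],
                    "point_b": point_b[name],
                    "diff": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n_valid": nv,
                    "n_dropped": dropped,
                }
            )
            continue
        dv = d[valid]
        lo, hi = np.percentile(dv, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        p = min(
            1.0,
            2.0
            * min(
                (np.count_nonzero(dv <= 0) + 1) / (nv + 1),
                (np.count_nonzero(dv >= 0) + 1) / (nv + 1),
            ),
        )
        rows.append(
            {
                "statistic": name,
                "point_a": point_a[name],
                "point_b": point_b[name],
                "diff": point_a[name] - point_b[name],
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
                "n_valid": nv,
                "n_dropped": dropped,
            }
        )
    table = pd.DataFrame(rows).set_index("statistic")
    return ComparisonResult(table=table, diffs=diffs, alpha=alpha, B=B, seed=seed)
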