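"""Synthetic cohort generator calibrated to the published rearing summaries.

Raw per-individual rearing records for the sweetpotato weevil study are not
deposited, so the pipeline is exercised on simulated cohorts whose
summary statistics are calibrated to the published per-host means: stage
duration means and standard errors, per-stage completion probabilities, the
sex ratio at emergence, mean adult pre-oviposition period, lifetime
fecundity, oviposition-day counts and adult longevities.

Generative model per individual (one seeded generator drives everything):

* each pre-adult stage duration is a gamma draw matched to the stage's
  (mean, SD), discretised to whole days with a 1-day minimum;
* completing a stage is a Bernoulli trial; an individual that fails dies at
  a uniformly chosen day within its sampled stage duration;
* sex at adult emergence is Bernoulli(p_female);
* a female draws an adult longevity, a Poisson APOP, a gamma lifetime
  fecundity and a gamma oviposition-day count; her first egg falls APOP days
  after emergence and the remaining laying days are a uniform random subset
  of the early reproductive window of her adult life, each laying day
  receiving one egg plus a multinomial share of the remainder (the published
  tables give no daily schedule shape, so laying is uniform across
  oviposition days);
* a male draws an adult longevity and lays nothing.

Published summaries give means and SEs only, so the generator's SDs are
SE * sqrt(n) with the table's per-row n.  Fecundity and longevity are drawn
independently; any covariance between them in real cohorts is not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import math

import numpy as np
import yaml

from .cohort import Cohort, IndividualRecord, StageSchema

__all__ = [
    "WEEVIL_SCHEMA",
    "StageSim",
    "SyntheticParams",
    "ParameterError",
    "simulate_cohort",
    "table1_presets",
]

WEEVIL_SCHEMA = StageSchema(
    stages=("egg", "larva", "pupa", "female_adult", "male_adult"),
    reproductive_stages=("female_adult",),
    branch_point="pupa",
)


class ParameterError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass(frozen=True)
class StageSim:
    """Duration distribution (days) and completion probability of one stage."""

    mean: float
    sd: float
    completion: float


@dataclass
class SyntheticParams:
    """Full parameterisation of one simulated rearing cohort."""

    schema: StageSchema
    preadult: dict[str, StageSim]  # keyed by stage name, developmental order
    p_female: float
    apop_mean: float  # Poisson mean, days after adult emergence
    fecundity_mean: float
    fecundity_sd: float
    oviposition_days_mean: float
    oviposition_days_sd: float
    female_longevity_mean: float
    female_longevity_sd: float
    male_longevity_mean: float
    male_longevity_sd: float
    # laying days are drawn from the first `oviposition_window` days of adult
    # life (None = anywhere in adult life); real reproductive-value schedules
    # show laying confined to an early window of adult life, and spreading
    # eggs over the whole lifespan would badly delay the maternity schedule
    oviposition_window: float | None = None
    label: str = ""

    def validate(self) -> None:
        for stage, sim in self.preadult.items():
            if stage not in self.schema.stages:
                raise ParameterError(f"pre-adult stage {stage!r} not in schema")
            if sim.mean < 1 or sim.sd < 0:
                raise ParameterError(f"stage {stage!r}: need mean >= 1, sd >= 0")
            if not 0 <= sim.completion <= 1:
                raise ParameterError(f"stage {stage!r}: completion not in [0, 1]")
        if not 0 <= self.p_female <= 1:
            raise ParameterError("p_female must be in [0, 1]")
        if self.apop_mean < 0 or self.fecundity_mean < 0 or self.fecundity_sd < 0:
            raise ParameterError("APOP and fecundity parameters must be nonnegative")
        if self.oviposition_days_mean < 1 and self.fecundity_mean > 0:
            raise ParameterError("need at least one oviposition day when fecund")
        for nm, mean, sd in (
            ("female", self.female_longevity_mean, self.female_longevity_sd),
            ("male", self.male_longevity_mean, self.male_longevity_sd),
        ):
            if mean < 1 or sd < 0:
                raise ParameterError(f"{nm} longevity: need mean >= 1, sd >= 0")
        if self.oviposition_days_mean > self.female_longevity_mean:
            raise ParameterError(
                "mean oviposition days exceed mean female adult longevity"
            )
        if (
            self.oviposition_window is not None
            and self.oviposition_window < self.oviposition_days_mean
        ):
            raise ParameterError(
                "oviposition window shorter than the mean number of laying days"
            )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "label": self.label,
            "schema": {
                "stages": list(self.schema.stages),
                "reproductive_stages": list(self.schema.reproductive_stages),
                "branch_point": self.schema.branch_point,
            },
            "preadult": {
                s: {"mean": sim.mean, "sd": sim.sd, "completion": sim.completion}
                for s, sim in self.preadult.items()
            },
            "p_female": self.p_female,
            "apop_mean": self.apop_mean,
            "fecundity_mean": self.fecundity_mean,
            "fecundity_sd": self.fecundity_sd,
            "oviposition_days_mean": self.oviposition_days_mean,
            "oviposition_days_sd": self.oviposition_days_sd,
            "female_longevity_mean": self.female_longevity_mean,
            "female_longevity_sd": self.female_longevity_sd,
            "male_longevity_mean": self.male_longevity_mean,
            "male_longevity_sd": self.male_longevity_sd,
            "oviposition_window": self.oviposition_window,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticParams":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        schema = StageSchema(
            stages=tuple(data["schema"]["stages"]),
            reproductive_stages=tuple(data["schema"]["reproductive_stages"]),
            branch_point=data["schema"].get("branch_point"),
        )
        preadult = {
            s: StageSim(**vals) for s, vals in data["preadult"].items()
        }
        return cls(
            schema=schema,
            preadult=preadult,
            **{
                k: data[k]
                for k in (
                    "p_female",
                    "apop_mean",
                    "fecundity_mean",
                    "fecundity_sd",
                    "oviposition_days_mean",
                    "oviposition_days_sd",
                    "female_longevity_mean",
                    "female_longevity_sd",
                    "male_longevity_mean",
                    "male_longevity_sd",
                )
            },
            oviposition_window=data.get("oviposition_window"),
            label=data.get("label", ""),
        )


def _draw_duration(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Integer days >= 1 with (approximately) the requested mean and SD.

    A gamma variate matched to (mean - 1, sd) is rounded and shifted by one
    day, which keeps the requested mean under discretisation and enforces
    the 1-day minimum exactly.
    """
    if sd == 0:
        return max(1, round(mean))
    m = mean - 1.0
    if m <= 0:
        return 1
    shape = (m / sd) ** 2
    scale = sd * sd / m
    return 1 + int(round(rng.gamma(shape, scale)))


def _draw_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Integer >= 0 from a rounded gamma (degenerate when sd = 0)."""
    if mean <= 0:
        return 0
    if sd == 0:
        return round(mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return int(round(rng.gamma(shape, scale)))


def simulate_cohort(
    params: SyntheticParams, n: int, seed: int, label: str | None = None
) -> Cohort:
    """Simulate ``n`` independent individuals; deterministic for fixed seed."""
    if n < 1:
        raise ParameterError("n must be at least 1")
    params.validate()
    rng = np.random.default_rng(seed)
    schema = params.schema
    female_stage = schema.reproductive_stages[0]
    branch = set(schema.branch_stages)
    male_candidates = [s for s in branch if s != female_stage]
    male_stage = male_candidates[0] if male_candidates else None
    width = len(str(n))
    records: list[IndividualRecord] = []
    for i in range(n):
        days: list[tuple[str, int]] = []
        alive = True
        for stage in schema.stages:
            if stage not in params.preadult:
                continue
            sim = params.preadult[stage]
            dur = _draw_duration(rng, sim.mean, sim.sd)
            if rng.random() < sim.completion:
                days.extend((stage, 0) for _ in range(dur))
            else:
                death_day = int(rng.integers(1, dur + 1))
                days.extend((stage, 0) for _ in range(death_day))
                alive = False
                break
        if alive:
            is_female = rng.random() < params.p_female
            if is_female:
                L = _draw_duration(
                    rng, params.female_longevity_mean, params.female_longevity_sd
                )
                apop = min(int(rng.poisson(params.apop_mean)), L - 1)
                F = _draw_count(rng, params.fecundity_mean, params.fecundity_sd)
                eggs_by_day = np.zeros(L, dtype=int)
                if F > 0:
                    k = _draw_count(
                        rng,
                        params.oviposition_days_mean,
                        params.oviposition_days_sd,
                    )
                    last = L - 1
                    if params.oviposition_window is not None:
                        last = min(last, apop + int(round(params.oviposition_window)) - 1)
                    k = max(1, min(k, last - apop + 1, F))
                    lay_days = [apop]
                    if k > 1:
                        lay_days += list(
                            rng.choice(
                                np.arange(apop + 1, last + 1),
                                size=k - 1,
                                replace=False,
                            )
                        )
                    eggs_by_day[lay_days] = 1
                    if F > k:
                        eggs_by_day[lay_days] += rng.multinomial(
                            F - k, np.full(k, 1.0 / k)
                        )
                days.extend((female_stage, int(e)) for e in eggs_by_day)
            else:
                if male_stage is None:
                    raise ParameterError("schema has no male branch stage")
                L = _draw_duration(
                    rng, params.male_longevity_mean, params.male_longevity_sd
                )
                days.extend((male_stage, 0) for _ in range(L))
        records.append(IndividualRecord(id=f"i{i + 1:0{width}d}", days=days))
    return Cohort(
        schema=schema,
        records=records,
        label=label if label is not None else params.label,
    )


def _preset(host: str) -> SyntheticParams:
    sd = lambda se, n: se * math.sqrt(n)  # table prints SE; generator needs SD
    if host == "batatas":
        return SyntheticParams(
            schema=WEEVIL_SCHEMA,
            preadult={
                "egg": StageSim(4.86, sd(0.25, 149), 149 / 150),
                "larva": StageSim(37.08, sd(0.22, 146), 146 / 149),
                "pupa": StageSim(8.32, sd(0.15, 146), 1.0),
            },
            p_female=90 / 146,
            apop_mean=0.10,
            fecundity_mean=90.91,
            fecundity_sd=sd(0.98, 90),
            oviposition_days_mean=29.72,
            oviposition_days_sd=sd(0.19, 90),
            female_longevity_mean=87.87,
            female_longevity_sd=sd(1.11, 90),
            male_longevity_mean=88.77,
            male_longevity_sd=sd(1.32, 56),
            oviposition_window=42.0,
            label="Ipomoea batatas",
        )
    if host == "triloba":
        return SyntheticParams(
            schema=WEEVIL_SCHEMA,
            preadult={
                "egg": StageSim(5.93, sd(0.15, 150), 1.0),
                "larva": StageSim(54.87, sd(0.54, 150), 1.0),
                "pupa": StageSim(16.99, sd(0.29, 150), 1.0),
            },
            p_female=83 / 150,
            apop_mean=0.07,
            fecundity_mean=68.57,
            fecundity_sd=sd(1.24, 83),
            oviposition_days_mean=22.80,
            oviposition_days_sd=sd(0.17, 83),
            female_longevity_mean=57.41,
            female_longevity_sd=sd(0.95, 83),
            male_longevity_mean=56.25,
            male_longevity_sd=sd(1.47, 67),
            oviposition_window=39.0,
            label="Ipomoea triloba",
        )
    raise ParameterError(f"unknown host preset {host!r}")


def table1_presets(host: str) -> SyntheticParams:
    """Calibrated parameters for the two host plants.

    ``host`` is ``"batatas"`` (sweet potato, the major host: faster
    development, higher fecundity, 146/150 pre-adult survival, 90 of 146
    adults female) or ``"triloba"`` (the alternative host: slower
    development, lower fecundity, no observed pre-adult mortality, 83 of 150
    adults female).  Duration and count SDs are reconstructed from the
    published standard errors as SE * sqrt(n).
    """
    params = _preset(host)
    params.validate()
    return params
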