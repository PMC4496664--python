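"""Cohort data model and canonical long-format I/O.

The analysis consumes daily rearing records of a single cohort followed from
egg to death: one row per individual per day of age, recording the
developmental stage occupied at that day's census and the number of eggs laid
that day.  Age 0 is the day of oviposition and the last recorded day is the
last day the individual was observed alive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "StageSchema",
    "IndividualRecord",
    "Cohort",
    "StageCounts",
    "Violation",
    "CohortError",
    "CohortParseError",
    "StageSchemaError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "cohort_counts",
]

CSV_HEADER = "id,age,stage,eggs"


class CohortError(ValueError):
    """Base error for cohort construction and parsing."""


class CohortParseError(CohortError):
    """Malformed cohort file (missing/duplicate rows, bad values)."""


class StageSchemaError(CohortError):
    """Stage name or schema structure problem."""


@dataclass(frozen=True)
class StageSchema:
    """Ordered developmental stages with an optional terminal sex branch.

    ``stages`` lists every stage in developmental order.  If ``branch_point``
    is set, all stages after it are mutually exclusive terminal alternatives
    (e.g. pupa -> female_adult | male_adult); an individual enters at most one
    of them.  ``reproductive_stages`` are the only stages in which nonzero
    fecundity is allowed (the female adult stage in a two-sex table).
    """

    stages: tuple[str, ...]
    reproductive_stages: tuple[str, ...]
    branch_point: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(
            self, "reproductive_stages", tuple(self.reproductive_stages)
        )
        if len(self.stages) < 2:
            raise StageSchemaError("schema needs at least two stages")
        if len(set(self.stages)) != len(self.stages):
            raise StageSchemaError("stage names must be unique")
        if any(not s for s in self.stages):
            raise StageSchemaError("stage names must be nonempty")
        unknown = set(self.reproductive_stages) - set(self.stages)
        if unknown:
            raise StageSchemaError(f"reproductive stages not in schema: {unknown}")
        if self.branch_point is not None and self.branch_point not in self.stages:
            raise StageSchemaError(f"branch point {self.branch_point!r} not in schema")

    @property
    def m(self) -> int:
        """Number of stages."""
        return len(self.stages)

    def index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise StageSchemaError(f"unknown stage {stage!r}") from None

    @property
    def branch_stages(self) -> tuple[str, ...]:
        """Terminal alternative stages after the branch point (empty if none)."""
        if self.branch_point is None:
            return ()
        return self.stages[self.index(self.branch_point) + 1 :]

    @classmethod
    def from_file(cls, path: str | Path) -> "StageSchema":
        """Load a schema from a YAML or JSON file with keys
        ``stages``, ``reproductive_stages``, ``branch_point``."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls(
            stages=tuple(data["stages"]),
            reproductive_stages=tuple(data.get("reproductive_stages", ())),
            branch_point=data.get("branch_point"),
        )

    def to_file(self, path: str | Path) -> None:
        data = {
            "stages": list(self.stages),
            "reproductive_stages": list(self.reproductive_stages),
            "branch_point": self.branch_point,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


@dataclass
class IndividualRecord:
    """One individual's full daily life history.

    ``days[x]`` is the ``(stage, eggs)`` pair at age ``x`` (in days); the
    sequence runs from age 0 (oviposition) to the last day alive.
    """

    id: str
    days: list[tuple[str, int]]

    @property
    def last_age(self) -> int:
        return len(self.days) - 1

    def stage_at(self, age: int) -> str | None:
        if 0 <= age < len(self.days):
            return self.days[age][0]
        return None


@dataclass
class Cohort:
    """A reared cohort: schema, one record per initial individual, label."""

    schema: StageSchema
    records: list[IndividualRecord]
    label: str = ""

    @property
    def n(self) -> int:
        """Initial cohort size N."""
        return len(self.records)

    @property
    def max_age(self) -> int:
        """Highest observed age A (last day any individual was alive)."""
        if not self.records:
            raise CohortError("empty cohort has no maximum age")
        return max(r.last_age for r in self.records)


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_cohort`."""

    id: str
    age: int | None
    rule: str

    def __str__(self) -> str:
        loc = f"id={self.id}" + (f", age={self.age}" if self.age is not None else "")
        return f"{self.rule} ({loc})"


@dataclass
class StageCounts:
    """Completion counts: per-stage n, sex counts and initial size.

    ``completed[j]`` counts individuals that finished stage ``j`` — entered a
    later stage, or, for terminal (adult) stages, entered it at all (their
    residence runs to natural death).  ``n_female`` counts individuals ever
    observed in a reproductive-branch stage, regardless of egg production.
    """

    completed: dict[str, int]
    n: int
    n_female: int
    n_male: int


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every record against the schema invariants.

    Returns an empty list iff the cohort is valid; never raises.  Each
    violation names the individual, the age (when localised) and the rule.
    """
    schema = cohort.schema
    out: list[Violation] = []
    seen_ids: set[str] = set()
    stage_set = set(schema.stages)
    branch = set(schema.branch_stages)
    repro = set(schema.reproductive_stages)
    first_stage = schema.stages[0]
    for rec in cohort.records:
        if rec.id in seen_ids:
            out.append(Violation(rec.id, None, "duplicate individual id"))
        seen_ids.add(rec.id)
        if not rec.days:
            out.append(Violation(rec.id, None, "record has no days"))
            continue
        if rec.days[0][0] != first_stage:
            out.append(
                Violation(rec.id, 0, f"record must start in stage {first_stage!r}")
            )
        prev_idx = -1
        visited_branch: set[str] = set()
        for age, (stage, eggs) in enumerate(rec.days):
            if stage not in stage_set:
                out.append(Violation(rec.id, age, f"unknown stage {stage!r}"))
                continue
            idx = schema.index(stage)
            if idx < prev_idx:
                out.append(
                    Violation(rec.id, age, f"stage regression into {stage!r}")
                )
            prev_idx = max(prev_idx, idx)
            if stage in branch:
                visited_branch.add(stage)
            if not isinstance(eggs, (int,)) or eggs < 0:
                out.append(Violation(rec.id, age, "eggs must be a nonnegative integer"))
            elif eggs > 0 and stage not in repro:
                out.append(
                    Violation(rec.id, age, "fecundity outside reproductive stage")
                )
        if len(visited_branch) > 1:
            out.append(
                Violation(rec.id, None, "individual entered more than one branch stage")
            )
    return out


def _records_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = [
        (rec.id, age, stage, eggs)
        for rec in cohort.records
        for age, (stage, eggs) in enumerate(rec.days)
    ]
    df = pd.DataFrame(rows, columns=["id", "age", "stage", "eggs"])
    return df.sort_values(["id", "age"], kind="mergesort").reset_index(drop=True)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical long CSV (``id,age,stage,eggs``), sorted by (id, age)."""
    df = _records_to_frame(cohort)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(CSV_HEADER + "\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.id},{row.age},{row.stage},{row.eggs}\n")


def read_cohort(path: str | Path, schema: StageSchema, label: str = "") -> Cohort:
    """Read and validate a cohort from the canonical long CSV.

    Row order in the file never matters: records are assembled after sorting
    by (id, age).  Raises :class:`CohortParseError` on structural problems
    (duplicate or missing individual-days, bad header) and
    :class:`StageSchemaError` on unknown stage names; semantic invariant
    violations found by :func:`validate_cohort` also raise.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header != CSV_HEADER:
        raise CohortParseError(
            f"{path}: expected header {CSV_HEADER!r}, found {header!r}"
        )
    df = pd.read_csv(path, dtype={"id": str, "stage": str})
    if df.empty:
        return Cohort(schema=schema, records=[], label=label)
    if df[["id", "age"]].duplicated().any():
        dup = df[df[["id", "age"]].duplicated()].iloc[0]
        raise CohortParseError(
            f"{path}: duplicate (id, age) pair ({dup['id']}, {dup['age']})"
        )
    unknown = set(df["stage"]) - set(schema.stages)
    if unknown:
        raise StageSchemaError(f"{path}: unknown stage names {sorted(unknown)}")
    df = df.sort_values(["id", "age"], kind="mergesort")
    records = []
    for ind_id, grp in df.groupby("id", sort=True):
        ages = grp["age"].to_numpy()
        if ages[0] != 0 or (ages != range(len(ages))).any():
            raise CohortParseError(
                f"{path}: ages for id {ind_id} must be contiguous from 0"
            )
        days = list(zip(grp["stage"], (int(e) for e in grp["eggs"])))
        records.append(IndividualRecord(id=str(ind_id), days=days))
    cohort = Cohort(schema=schema, records=records, label=label)
    problems = validate_cohort(cohort)
    if problems:
        raise CohortError(
            "invalid cohort: " + "; ".join(str(p) for p in problems[:5])
        )
    return cohort


def cohort_counts(cohort: Cohort) -> StageCounts:
    """Per-stage completion counts plus N, N_f (females) and N_m (males).

    A non-terminal stage is completed when the individual is later observed in
    any subsequent stage; a terminal stage (after the branch point, or the
    last stage of an unbranched schema) is counted for every individual that
    reached it.
    """
    schema = cohort.schema
    branch = set(schema.branch_stages)
    terminal = branch if branch else {schema.stages[-1]}
    repro = set(schema.reproductive_stages)
    completed = {s: 0 for s in schema.stages}
    n_female = 0
    n_male = 0
    for rec in cohort.records:
        stages_seen = []
        for stage, _ in rec.days:
            if not stages_seen or stages_seen[-1] != stage:
                stages_seen.append(stage)
        for i, stage in enumerate(stages_seen):
            if stage in terminal or i < len(stages_seen) - 1:
                completed[stage] += 1
        reached = set(stages_seen)
        if reached & branch & repro or (not branch and reached & repro):
            n_female += 1
        elif reached & (branch - repro):
            n_male += 1
    return StageCounts(
        completed=completed, n=cohort.n, n_female=n_female, n_male=n_male
    )
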