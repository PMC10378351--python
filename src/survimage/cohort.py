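"""Cohort assembly, exclusion rules, and age-stratified train/test splits.

The modeling cohort is built from a raw clinical table by three ordered
exclusion stages:

1. records missing age or survival time (or with a negative survival time,
   which cannot be ordered) are dropped;
2. every record whose survival time is shared with at least one other record
   is dropped — whole tie groups, not deduplicated — so that survival times
   are pairwise distinct afterwards and pair orientation never needs a
   tie-break;
3. optionally, records without an actual date of death are dropped, removing
   the censoring artifact where "survival" is really a last-follow-up date.

Splitting is stratified by an age cutoff (age ≤ cutoff vs older): ids are
shuffled within each stratum with a seeded RNG and the first ``train_frac``
share is assigned to training.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "ClinicalRecord",
    "Cohort",
    "FilterReport",
    "SplitSpec",
    "CohortError",
    "read_clinical",
    "write_clinical",
    "filter_cohort",
    "stratified_split",
]


class CohortError(ValueError):
    """Raised for invalid cohort inputs or degenerate splits."""


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample clinical metadata.

    ``age_years`` and ``survival_days`` may be ``None`` in a raw (pre-filter)
    cohort; :func:`filter_cohort` rejects such records at its first stage.
    ``has_death_date`` distinguishes an actual recorded death from a
    last-follow-up survival value.
    """

    sample_id: str
    age_years: int | None
    survival_days: int | None
    has_death_date: bool
    race: str | None = None


@dataclass
class Cohort:
    """Clinical records paired one-to-one with expression columns."""

    records: list[ClinicalRecord]
    expression: ExpressionMatrix

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate sample_id in cohort records")
        if ids != list(self.expression.sample_ids):
            if set(ids) != set(self.expression.sample_ids):
                raise CohortError(
                    "clinical records and expression columns cover different samples"
                )
            # align column order to record order
            self.expression = self.expression.subset(ids)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def record(self, sample_id: str) -> ClinicalRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def survival_of(self, sample_id: str) -> int:
        days = self.record(sample_id).survival_days
        if days is None:
            raise CohortError(f"sample {sample_id!r} has no survival time")
        return days

    def age_of(self, sample_id: str) -> int:
        age = self.record(sample_id).age_years
        if age is None:
            raise CohortError(f"sample {sample_id!r} has no age")
        return age

    def subset(self, sample_ids: list[str]) -> "Cohort":
        recs = {r.sample_id: r for r in self.records}
        return Cohort(
            records=[recs[sid] for sid in sample_ids],
            expression=self.expression.subset(list(sample_ids)),
        )


@dataclass(frozen=True)
class FilterReport:
    """Per-stage bookkeeping for :func:`filter_cohort`.

    ``stage_survivors`` holds the cohort size after each of the three stages,
    so exclusions are additive: ``n_input = n_output + sum(excluded)``.
    """

    n_input: int
    excluded_missing_clinical: int
    excluded_tied_survival: int
    excluded_no_death_date: int
    stage_survivors: tuple[int, int, int]

    @property
    def n_output(self) -> int:
        return self.stage_survivors[-1]


def filter_cohort(
    raw: Cohort, require_death_date: bool = True
) -> tuple[Cohort, FilterReport]:
    """Apply the three exclusion stages and report per-stage counts.

    Stage 2 drops *all* members of every survival-time tie group, which
    guarantees a strict total order on survival afterwards.

    Raises
    ------
    CohortError
        If no record survives filtering.
    """
    n_input = len(raw.records)

    stage1 = [
        r
        for r in raw.records
        if r.age_years is not None
        and r.survival_days is not None
        and r.survival_days >= 0
    ]
    n1 = len(stage1)

    counts: dict[int, int] = {}
    for r in stage1:
        counts[r.survival_days] = counts.get(r.survival_days, 0) + 1
    stage2 = [r for r in stage1 if counts[r.survival_days] == 1]
    n2 = len(stage2)

    if require_death_date:
        stage3 = [r for r in stage2 if r.has_death_date]
    else:
        stage3 = stage2
    n3 = len(stage3)

    if n3 == 0:
        raise CohortError("no samples survive filtering")

    report = FilterReport(
        n_input=n_input,
        excluded_missing_clinical=n_input - n1,
        excluded_tied_survival=n1 - n2,
        excluded_no_death_date=n2 - n3,
        stage_survivors=(n1, n2, n3),
    )
    kept = [r.sample_id for r in stage3]
    return raw.subset(kept), report


@dataclass(frozen=True)
class SplitSpec:
    """Deterministic stratified train/test assignment.

    ``stratum_of`` maps every sample id to ``"YOUNG"`` (age ≤ cutoff) or
    ``"OLD"`` (age > cutoff).
    """

    cutoff_age: int
    seed: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    stratum_of: dict[str, str] = field(hash=False)

    def train_of(self, stratum: str) -> list[str]:
        return [s for s in self.train_ids if self.stratum_of[s] == stratum]

    def test_of(self, stratum: str) -> list[str]:
        return [s for s in self.test_ids if self.stratum_of[s] == stratum]


def _train_count(n: int, frac: float, rounding: str) -> int:
    if rounding == "ceil":
        k = math.ceil(frac * n)
    elif rounding == "floor":
        k = math.floor(frac * n)
    elif rounding == "round":  # round half up
        k = math.floor(frac * n + 0.5)
    else:
        raise CohortError(f"unknown rounding rule {rounding!r}")
    # both sides of the split must be non-empty
    return min(max(k, 1), n - 1)


def stratified_split(
    c: Cohort,
    cutoff_age: int,
    train_frac: float = 0.7,
    seed: int = 0,
    rounding: str = "ceil",
) -> SplitSpec:
    """Shuffle each age stratum with a seeded RNG and take the leading share.

    Within each stratum the ids are sorted, shuffled by ``random.Random(seed)``
    (independently re-seeded per stratum so the assignment in one stratum does
    not perturb the other), and the first ``round(train_frac * n)`` become the
    training set, with the rounding rule configurable (``ceil`` — the default,
    matching realized 70/30 cohort sizes — ``floor``, or round-half-up
    ``round``).

    Raises
    ------
    CohortError
        If ``train_frac`` is not in (0, 1) or a stratum has fewer than two
        members (both sides of the split must be populated in each stratum).
    """
    if not 0.0 < train_frac < 1.0:
        raise CohortError(f"train_frac must be in (0, 1), got {train_frac}")
    if c.n == 0:
        raise CohortError("cannot split an empty cohort")

    strata: dict[str, list[str]] = {"YOUNG": [], "OLD": []}
    stratum_of: dict[str, str] = {}
    for r in c.records:
        if r.age_years is None:
            raise CohortError(f"sample {r.sample_id!r} has no age; filter first")
        s = "YOUNG" if r.age_years <= cutoff_age else "OLD"
        strata[s].append(r.sample_id)
        stratum_of[r.sample_id] = s

    train: list[str] = []
    test: list[str] = []
    for name in ("YOUNG", "OLD"):
        members = sorted(strata[name])
        if len(members) < 2:
            raise CohortError(
                f"stratum {name} at cutoff {cutoff_age} has {len(members)} "
                "member(s); need at least 2"
            )
        rng = random.Random(f"{seed}:{name}")
        rng.shuffle(members)
        k = _train_count(len(members), train_frac, rounding)
        train.extend(members[:k])
        test.extend(members[k:])

    return SplitSpec(
        cutoff_age=cutoff_age,
        seed=seed,
        train_ids=tuple(train),
        test_ids=tuple(test),
        stratum_of=stratum_of,
    )


def read_clinical(path) -> list[ClinicalRecord]:
    """Read a clinical TSV with columns
    ``sample_id, age_at_index, survival_days, death_date, race``.

    Empty cells mean the field is absent; an empty ``death_date`` means no
    actual death date was recorded.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "age_at_index", "survival_days", "death_date"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"clinical table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age_at_index")
        surv = getattr(row, "survival_days")
        death = getattr(row, "death_date")
        race = getattr(row, "race", None)
        records.append(
            ClinicalRecord(
                sample_id=str(row.sample_id),
                age_years=int(float(age)) if pd.notna(age) and age != "" else None,
                survival_days=int(float(surv)) if pd.notna(surv) and surv != "" else None,
                has_death_date=bool(pd.notna(death) and str(death) != ""),
                race=str(race) if pd.notna(race) and race != "" else None,
            )
        )
    return records


def write_clinical(records: list[ClinicalRecord], path) -> None:
    """Write records to the TSV layout read by :func:`read_clinical`."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "age_at_index": [r.age_years for r in records],
            "survival_days": [r.survival_days for r in records],
            "death_date": ["recorded" if r.has_death_date else "" for r in records],
            "race": [r.race for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
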