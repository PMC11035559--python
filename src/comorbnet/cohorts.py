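"""First-diagnosis ages and 10-year age-gender cohorts.

A patient's diagnostic history is reduced to one record per (patient, code)
pair carrying the age at which the code was *first* recorded.  Patients are
then stratified into 10-year age-gender cohorts (0-9, 10-19, ..., 80+):
a patient belongs to cohort decade D when at least one of their codes was
first diagnosed at an age inside D, and within that cohort carries their
*cumulative* history — every code first diagnosed at or before the decade's
upper bound.  A patient first diagnosed with code 1 at 56 and code 2 at 63
is therefore in the 50-59 cohort with {code 1} and in the 60-69 cohort with
{code 1, code 2}.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .records_io import DiagnosisEvent, Gender

__all__ = [
    "FirstDiagnosis",
    "Decade",
    "CohortDataset",
    "GenderConflictError",
    "first_diagnosis_ages",
    "build_cohorts",
    "TOP_DECADE",
]

#: lower bound of the open-ended top age bucket ("80-XX")
TOP_DECADE = 80


class GenderConflictError(ValueError):
    def __init__(self, patients: list[str]):
        self.patients = patients
        super().__init__(f"patients recorded with two genders: {patients}")


@dataclass(frozen=True, order=True)
class FirstDiagnosis:
    patient_id: str
    gender: Gender
    icd_code: str
    age_first: int


@dataclass(frozen=True, order=True)
class Decade:
    """Inclusive integer age bracket [lo, hi]; the top bucket is open-ended."""

    lo: int
    hi: int | None  # None = unbounded ("80-XX")

    @classmethod
    def of_age(cls, age: int) -> "Decade":
        if age >= TOP_DECADE:
            return cls(TOP_DECADE, None)
        lo = (age // 10) * 10
        return cls(lo, lo + 9)

    def contains(self, age: int) -> bool:
        return age >= self.lo and (self.hi is None or age <= self.hi)

    @property
    def upper(self) -> float:
        return float("inf") if self.hi is None else self.hi

    @property
    def label(self) -> str:
        return f"{self.lo}-XX" if self.hi is None else f"{self.lo}-{self.hi}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class CohortDataset:
    """One (gender, decade) slice: patient -> cumulative set of codes."""

    gender: Gender
    decade: Decade
    histories: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.histories)

    @property
    def key(self) -> tuple[str, str]:
        return (self.gender.value, self.decade.label)


def first_diagnosis_ages(events: Iterable[DiagnosisEvent]) -> list[FirstDiagnosis]:
    """Reduce events to one record per (patient, code) at the minimum age.

    Raises :class:`GenderConflictError` if any patient appears under both
    genders.
    """
    ages: dict[tuple[str, str], int] = {}
    genders: dict[str, Gender] = {}
    conflicts: set[str] = set()
    for ev in events:
        prev = genders.setdefault(ev.patient_id, ev.gender)
        if prev != ev.gender:
            conflicts.add(ev.patient_id)
        key = (ev.patient_id, ev.icd_code)
        if key not in ages or ev.age_at_event < ages[key]:
            ages[key] = ev.age_at_event
    if conflicts:
        raise GenderConflictError(sorted(conflicts))
    return [
        FirstDiagnosis(pid, genders[pid], code, age)
        for (pid, code), age in sorted(ages.items())
    ]


def build_cohorts(
    first_dx: Iterable[FirstDiagnosis],
    carry_forward: bool = False,
) -> list[CohortDataset]:
    """Assemble 10-year age-gender cohorts with cumulative histories.

    By default a patient is a member of decade D only when some code of
    theirs was first diagnosed inside D.  With ``carry_forward=True`` the
    patient is additionally a member of every decade between their first
    and last first-diagnosis decades, whether or not a new code appeared
    there (their cumulative history at that decade's upper bound either
    way).  Cohorts with zero patients are omitted; output is sorted by
    (gender, decade).
    """
    by_patient: dict[tuple[str, Gender], list[FirstDiagnosis]] = defaultdict(list)
    for fd in first_dx:
        by_patient[(fd.patient_id, fd.gender)].append(fd)

    cohorts: dict[tuple[Gender, Decade], dict[str, frozenset[str]]] = defaultdict(dict)
    for (pid, gender), records in by_patient.items():
        decades = {Decade.of_age(r.age_first) for r in records}
        if carry_forward:
            lo = min(d.lo for d in decades)
            hi = max(d.lo for d in decades)
            decades = {Decade.of_age(a) for a in range(lo, hi + 1, 10)}
        for dec in decades:
            history = frozenset(r.icd_code for r in records if r.age_first <= dec.upper)
            cohorts[(gender, dec)][pid] = history

    return [
        CohortDataset(gender, dec, dict(sorted(hist.items())))
        for (gender, dec), hist in sorted(
            cohorts.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        )
    ]


def cohort_manifest(cohorts: Iterable[CohortDataset]) -> dict:
    """Sizes and decades present, for the run manifest / cohort export."""
    return {
        "cohorts": [
            {
                "gender": c.gender.value,
                "decade": c.decade.label,
                "n_patients": c.n_patients,
                "n_codes": len(set().union(*c.histories.values())) if c.histories else 0,
            }
            for c in cohorts
        ]
    }
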