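"""Incident-antidepressant-user cohort selection with an exclusion audit trail.

A patient enters the cohort at the first-ever antidepressant dispensing (the
index event) if, on that day, they were 6–17 years old and had at least six
months (183 days) of database history. Three further filters remove likely
non-psychiatric indications:

* *bed-wetting*: starters of amitriptyline or imipramine who received
  desmopressin (H01BA02) at any time;
* *pain*: tricyclic starters with two or more pain-related dispensings
  (M01, N02, gabapentin N03AX12, pregabalin N03AX16) in the 183 days before
  the index day (the index day itself is not counted);
* *same-day dual start*: two different antidepressants dispensed on the
  index day.

Rules are evaluated in a fixed order (window → age → history → dual →
bed-wetting → pain) and each excluded patient is reported once, under the
first rule triggered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Union

from .codes import BEDWETTING_TCAS, DESMOPRESSIN, PAIN_EXACT, PAIN_PREFIXES, is_antidepressant
from .io import Dataset, PrescriptionRecord

DAYS_PER_YEAR = 365.25

EXCLUSION_RULES = ("age", "history", "same_day_dual", "bedwetting", "pain",
                   "prior_antidepressant")


@dataclass(frozen=True)
class CohortConfig:
    study_start: date = date(1994, 1, 1)
    study_end: date = date(2014, 12, 31)
    history_days: int = 183          # "at least 6 months" of database history
    pain_window_days: int = 183
    pain_min_count: int = 2
    age_min: int = 6
    age_max: int = 17
    age_from_year_only: bool = False  # fall back to index year - birth year
    # (label, first floor-age, last floor-age)
    age_bands: tuple = (("child", 6, 9), ("preteen", 10, 13), ("teen", 14, 17))
    # (label, first calendar year, last calendar year)
    periods: tuple = (("1994-2003", 1994, 2003), ("2004-2009", 2004, 2009),
                      ("2010-2014", 2010, 2014))


DEFAULT_CONFIG = CohortConfig()


@dataclass(frozen=True)
class CohortEntry:
    patient_id: str
    index_date: date
    index_atc: str
    age_years: float
    age_group: str
    period: str
    prescriber: str
    index_records: tuple = field(default=(), compare=False)


@dataclass(frozen=True)
class ExclusionRecord:
    patient_id: str
    rule: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.rule not in EXCLUSION_RULES:
            raise ValueError(f"unknown exclusion rule {self.rule!r}")


def age_at(birth_date: date, on: date, from_year_only: bool = False) -> float:
    """Age in years at a date; exact-date variant uses days / 365.25."""
    if from_year_only:
        return float(on.year - birth_date.year)
    return (on - birth_date).days / DAYS_PER_YEAR


def assign_age_group(age_years: float, config: CohortConfig = DEFAULT_CONFIG) -> str:
    whole = int(age_years)
    for label, lo, hi in config.age_bands:
        if lo <= whole <= hi:
            return label
    raise ValueError(f"age {age_years} outside the configured bands")


def assign_period(on: date, config: CohortConfig = DEFAULT_CONFIG) -> str:
    for label, first, last in config.periods:
        if first <= on.year <= last:
            return label
    raise ValueError(f"{on.isoformat()} outside the configured study periods")


def find_index_event(dataset: Dataset, patient_id: str):
    """Earliest antidepressant fill date and the set of distinct ATC codes
    filled that day; None if the patient has no antidepressant record."""
    fills = [r for r in dataset.prescriptions_for(patient_id)
             if is_antidepressant(r.atc_code)]
    if not fills:
        return None
    index_date = min(r.fill_date for r in fills)
    atcs = frozenset(r.atc_code for r in fills if r.fill_date == index_date)
    return index_date, atcs


def apply_inclusion(dataset: Dataset, patient_id: str, index_event,
                    config: CohortConfig = DEFAULT_CONFIG
                    ) -> Union[CohortEntry, ExclusionRecord]:
    """Age / history / same-day-dual checks on an index event."""
    index_date, atcs = index_event
    patient = dataset.patients[patient_id]
    if not (config.study_start <= index_date <= config.study_end):
        return ExclusionRecord(patient_id, "history", "outside window")
    age = age_at(patient.birth_date, index_date, config.age_from_year_only)
    if not (config.age_min <= int(age) <= config.age_max):
        return ExclusionRecord(patient_id, "age", f"age {age:.1f} at index")
    history = (index_date - patient.db_entry_date).days
    if history < config.history_days:
        return ExclusionRecord(patient_id, "history",
                               f"{history} days of history")
    if len(atcs) > 1:
        return ExclusionRecord(patient_id, "same_day_dual",
                               "index drugs: " + ", ".join(sorted(atcs)))
    index_atc = next(iter(atcs))
    index_records = tuple(
        r for r in dataset.prescriptions_for(patient_id)
        if r.fill_date == index_date and r.atc_code == index_atc
    )
    return CohortEntry(
        patient_id=patient_id,
        index_date=index_date,
        index_atc=index_atc,
        age_years=age,
        age_group=assign_age_group(age, config),
        period=assign_period(index_date, config),
        prescriber=index_records[0].prescriber,
        index_records=index_records,
    )


def exclude_bedwetting(dataset: Dataset, entry: CohortEntry
                       ) -> Union[CohortEntry, ExclusionRecord]:
    """Amitriptyline/imipramine starters with desmopressin at any time."""
    if entry.index_atc not in BEDWETTING_TCAS:
        return entry
    for r in dataset.prescriptions_for(entry.patient_id):
        if r.atc_code.startswith(DESMOPRESSIN):
            return ExclusionRecord(entry.patient_id, "bedwetting",
                                   f"desmopressin on {r.fill_date.isoformat()}")
    return entry


def _is_pain_related(record: PrescriptionRecord) -> bool:
    return (record.atc_code.startswith(PAIN_PREFIXES)
            or record.atc_code in PAIN_EXACT)


def exclude_pain(dataset: Dataset, entry: CohortEntry,
                 config: CohortConfig = DEFAULT_CONFIG
                 ) -> Union[CohortEntry, ExclusionRecord]:
    """Tricyclic starters with >= 2 pain-related fills in the prior window.

    The window is [index - pain_window_days, index - 1]: "prior to initiation"
    is read as excluding the index day itself.
    """
    if not entry.index_atc.startswith("N06AA"):
        return entry
    lo = entry.index_date - timedelta(days=config.pain_window_days)
    hi = entry.index_date - timedelta(days=1)
    n = sum(1 for r in dataset.prescriptions_for(entry.patient_id)
            if _is_pain_related(r) and lo <= r.fill_date <= hi)
    if n >= config.pain_min_count:
        return ExclusionRecord(entry.patient_id, "pain",
                               f"{n} pain-related fills in prior window")
    return entry


def build_cohort(dataset: Dataset, config: CohortConfig = DEFAULT_CONFIG
                 ) -> tuple[list[CohortEntry], list[ExclusionRecord]]:
    """Run the full selection; every patient with an antidepressant record
    lands in exactly one of the two output lists."""
    entries: list[CohortEntry] = []
    exclusions: list[ExclusionRecord] = []
    for patient_id in sorted(dataset.patients):
        index_event = find_index_event(dataset, patient_id)
        if index_event is None:
            continue
        result = apply_inclusion(dataset, patient_id, index_event, config)
        if isinstance(result, CohortEntry):
            result = exclude_bedwetting(dataset, result)
        if isinstance(result, CohortEntry):
            result = exclude_pain(dataset, result, config)
        if isinstance(result, CohortEntry):
            entries.append(result)
        else:
            exclusions.append(result)
    return entries, exclusions


def exclusion_counts(exclusions: list[ExclusionRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for e in exclusions:
        counts[e.rule] = counts.get(e.rule, 0) + 1
    return counts
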