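"""Dose classification against pediatric prescribing guidelines.

Three rulesets are shipped, all expressed in DDD/day:

* ``dutch_lenient`` — starting doses of 0.25 DDD for fluoxetine (5 mg),
  citalopram (5 mg) and fluvoxamine (25 mg); sertraline 0.5 DDD (25 mg) for
  children under 13 and 1 DDD (50 mg) from the 13th birthday.
* ``dutch_strict`` — as above but sertraline stays at 0.5 DDD for all ages.
* ``uk`` — the international check that fluoxetine starts at 10 mg or less
  (0.5 DDD), any age.

A starting dose is compliant when it is *at or below* the threshold for the
drug and age (closed comparison). Independently, any dose at or above
1 DDD/day is flagged as an adult dose; both flags can be true at once
(e.g. sertraline in teens). Maintenance compliance uses configurable
[low, high] ranges; the shipped defaults — [guideline starting dose,
1 DDD/day] — are this package's convention, since published guidance rarely
prints explicit maintenance bounds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .doses import DoseResult
from .maintenance import MaintenanceEpisode

ADULT_DOSE_DDD = 1.0
RULESETS = ("dutch_lenient", "dutch_strict", "uk")


@dataclass(frozen=True)
class GuidelineRule:
    ruleset: str
    atc_code: str
    min_age: int  # inclusive bounds on floor(age)
    max_age: int
    max_start_ddd: float
    maint_low_ddd: float
    maint_high_ddd: float


@dataclass(frozen=True)
class ComplianceResult:
    patient_id: str
    atc_code: str
    compliant: bool | None  # None when the drug is not covered by the ruleset
    adult_dose: bool
    ruleset: str


def load_rules(path=None) -> list[GuidelineRule]:
    """Load guideline rules from the shipped (or a user-supplied) CSV."""
    if path is None:
        source = resources.files("rxcohort.data").joinpath("guideline_rules.csv")
        fh = source.open("r", newline="")
    else:
        fh = open(path, newline="")
    rules = []
    with fh:
        for row in csv.DictReader(fh):
            rules.append(GuidelineRule(
                ruleset=row["ruleset"],
                atc_code=row["atc_code"],
                min_age=int(row["min_age"]),
                max_age=int(row["max_age"]),
                max_start_ddd=float(row["max_start_ddd"]),
                maint_low_ddd=float(row["maint_low_ddd"]),
                maint_high_ddd=float(row["maint_high_ddd"]),
            ))
    return rules


def default_rules(ruleset: str) -> list[GuidelineRule]:
    if ruleset not in RULESETS:
        raise ValueError(f"unknown ruleset {ruleset!r}; expected one of {RULESETS}")
    return [r for r in load_rules() if r.ruleset == ruleset]


def find_rule(rules: Sequence[GuidelineRule], atc_code: str,
              age_years: float) -> GuidelineRule | None:
    whole = int(age_years)
    for rule in rules:
        if atc_code.startswith(rule.atc_code) and rule.min_age <= whole <= rule.max_age:
            return rule
    return None


def classify_start(dose: DoseResult, age_years: float,
                   ruleset: str = "dutch_lenient",
                   rules: Sequence[GuidelineRule] | None = None
                   ) -> ComplianceResult:
    """Compliance (dose <= threshold) and adult-dose (>= 1 DDD/day) flags.

    The adult-dose flag is computed for every drug; compliance only for drugs
    the ruleset covers (None otherwise).
    """
    if not dose.is_valid or dose.dose_ddd_per_day is None:
        raise ValueError("classification requires a valid dose")
    if rules is None:
        rules = default_rules(ruleset)
    rule = find_rule(rules, dose.atc_code, age_years)
    compliant = None if rule is None else dose.dose_ddd_per_day <= rule.max_start_ddd
    return ComplianceResult(
        patient_id=dose.patient_id,
        atc_code=dose.atc_code,
        compliant=compliant,
        adult_dose=dose.dose_ddd_per_day >= ADULT_DOSE_DDD,
        ruleset=ruleset,
    )


def classify_maintenance(episode: MaintenanceEpisode, age_years: float,
                         ruleset: str = "dutch_lenient",
                         rules: Sequence[GuidelineRule] | None = None
                         ) -> ComplianceResult:
    """Maintenance compliance: dose within the closed [low, high] range."""
    if rules is None:
        rules = default_rules(ruleset)
    rule = find_rule(rules, episode.atc_code, age_years)
    compliant = None
    if rule is not None:
        compliant = rule.maint_low_ddd <= episode.dose_ddd_per_day <= rule.maint_high_ddd
    return ComplianceResult(
        patient_id=episode.patient_id,
        atc_code=episode.atc_code,
        compliant=compliant,
        adult_dose=episode.dose_ddd_per_day >= ADULT_DOSE_DDD,
        ruleset=ruleset,
    )
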