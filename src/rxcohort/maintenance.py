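"""Maintenance-episode detection from refill chains and titration classification.

A maintenance episode is a run of at least two consecutive prescriptions for
the same drug at the same dose (DDD/day, compared with a 1e-9 tolerance),
where each prescription's supply — extended by a 25 % grace allowance for
imperfect adherence — covers the fill date of the next, and the run's summed
days supply is at least 60. Missing per-prescription doses are set to 0;
runs at 0 DDD/day or above 4 DDD/day are discarded as data-entry errors.

When a patient has several episodes, the primary one is the longest (by total
days supply, or calendar span if configured), with the highest dose breaking
duration ties and the earliest start breaking any remainder. Titration
compares the primary maintenance dose against the valid starting dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

from .doses import DoseResult, days_supply, dose_or_zero
from .io import PrescriptionRecord

DOSE_TOL = 1e-9
GRACE_FRACTION = 0.25
MIN_SUPPLY_DAYS = 60.0
MIN_PRESCRIPTIONS = 2
MAX_MAINTENANCE_DOSE = 4.0


@dataclass(frozen=True)
class MaintenanceEpisode:
    patient_id: str
    atc_code: str
    dose_ddd_per_day: float
    start_date: date
    n_prescriptions: int
    total_days_supply: float
    duration_days: float  # last covered day - start_date


@dataclass(frozen=True)
class TitrationResult:
    patient_id: str
    direction: str  # same | up | down


def covers_next(record_a: PrescriptionRecord, record_b: PrescriptionRecord,
                grace: float = GRACE_FRACTION) -> bool:
    """True iff a's supply, stretched by the grace fraction, reaches b's fill date."""
    gap_days = (record_b.fill_date - record_a.fill_date).days
    supply = days_supply(record_a) or 0.0
    return gap_days <= supply * (1.0 + grace)


def _sort_key(r: PrescriptionRecord):
    return (r.fill_date, dose_or_zero(r), r.units_total)


def detect_episodes(records: Sequence[PrescriptionRecord], *,
                    tol: float = DOSE_TOL,
                    grace: float = GRACE_FRACTION,
                    min_supply_days: float = MIN_SUPPLY_DAYS,
                    min_prescriptions: int = MIN_PRESCRIPTIONS,
                    max_dose: float = MAX_MAINTENANCE_DOSE
                    ) -> list[MaintenanceEpisode]:
    """All maintenance episodes among one patient's fills of one drug.

    Records are sorted canonically by (fill date, dose, units); maximal runs
    are built by splitting whenever the dose changes (beyond ``tol``) or the
    previous fill — with grace — no longer covers the next fill date. A dose
    change terminates a run even if refills still overlap, because a
    maintenance period is defined by a constant dose. Each prescription
    therefore belongs to at most one maximal run.
    """
    if not records:
        return []
    rows = sorted(records, key=_sort_key)
    runs: list[list[PrescriptionRecord]] = [[rows[0]]]
    for prev, cur in zip(rows, rows[1:]):
        same_dose = abs(dose_or_zero(prev) - dose_or_zero(cur)) <= tol
        if same_dose and covers_next(prev, cur, grace):
            runs[-1].append(cur)
        else:
            runs.append([cur])
    episodes = []
    for run in runs:
        if len(run) < min_prescriptions:
            continue
        supply = sum(days_supply(r) or 0.0 for r in run)
        if supply < min_supply_days:
            continue
        dose = dose_or_zero(run[0])
        if not (0.0 < dose <= max_dose):
            continue
        last = run[-1]
        episodes.append(MaintenanceEpisode(
            patient_id=run[0].patient_id,
            atc_code=run[0].atc_code,
            dose_ddd_per_day=dose,
            start_date=run[0].fill_date,
            n_prescriptions=len(run),
            total_days_supply=supply,
            duration_days=(last.fill_date - run[0].fill_date).days
            + (days_supply(last) or 0.0),
        ))
    return episodes


def select_primary_episode(episodes: Sequence[MaintenanceEpisode],
                           duration_mode: str = "supply"
                           ) -> MaintenanceEpisode | None:
    """Longest episode, highest dose on duration ties, earliest start after that."""
    if not episodes:
        return None
    if duration_mode not in ("supply", "calendar"):
        raise ValueError(f"unknown duration_mode {duration_mode!r}")

    def key(ep: MaintenanceEpisode):
        duration = (ep.total_days_supply if duration_mode == "supply"
                    else ep.duration_days)
        return (duration, ep.dose_ddd_per_day, -ep.start_date.toordinal())

    return max(episodes, key=key)


def classify_titration(starting: DoseResult, maintenance: MaintenanceEpisode,
                       tol: float = DOSE_TOL) -> TitrationResult:
    """up / down / same relative to the valid starting dose."""
    if not starting.is_valid or starting.dose_ddd_per_day is None:
        raise ValueError("titration requires a valid starting dose")
    delta = maintenance.dose_ddd_per_day - starting.dose_ddd_per_day
    if delta > tol:
        direction = "up"
    elif delta < -tol:
        direction = "down"
    else:
        direction = "same"
    return TitrationResult(starting.patient_id, direction)
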