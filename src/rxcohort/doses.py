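"""Days-supply and DDD/day arithmetic, starting-dose rules, mg↔DDD conversion.

The defined daily dose (DDD) is the WHO's assumed average adult maintenance
dose for a drug's main indication; expressing every prescription as DDD/day
makes doses comparable across substances. For one dispensing:

    days supply = units dispensed / units to take per day
    dose (DDD/day) = total DDDs in the prescription / days supply

For the highly concentrated oral solutions of citalopram and escitalopram the
recorded daily dose is in drops, 20 drops ≈ 1 ml, so the daily dose is divided
by 20 before computing days supply. The constant is part of the published
method, not a tuning knob.

Plausibility filters: a computed dose of exactly 0 (typically a data-entry
error of 0 units per day) is "too low"; a starting dose above 3 DDD/day or a
maintenance dose above 4 DDD/day is "too high"; an uncomputable dose (missing
daily dose or missing total DDDs) is "missing". Boundary values 3.0 / 4.0 are
valid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .codes import ATC_BY_NAME, LIQUID_CONCENTRATE_ATCS
from .io import PrescriptionRecord

#: drops per ml for the concentrated liquid correction (1 drop ≈ 0.05 ml).
DROPS_PER_ML = 20.0

MAX_STARTING_DDD = 3.0
MAX_MAINTENANCE_DDD = 4.0


class UnknownDrugError(KeyError):
    """Raised when a drug is absent from the DDD table."""


@dataclass(frozen=True)
class DddTable:
    """Mapping from ATC code (or substance name) to mg per 1 DDD."""

    mg_per_ddd: dict[str, float]

    def __post_init__(self) -> None:
        for key, mg in self.mg_per_ddd.items():
            if not mg > 0:
                raise ValueError(f"mg per DDD must be > 0 for {key!r}")

    def lookup(self, atc_or_name: str) -> float:
        key = atc_or_name if atc_or_name in self.mg_per_ddd else atc_or_name.lower()
        if key not in self.mg_per_ddd:
            key = ATC_BY_NAME.get(atc_or_name.lower(), "")
        if key not in self.mg_per_ddd:
            raise UnknownDrugError(f"drug not in DDD table: {atc_or_name!r}")
        return self.mg_per_ddd[key]


def load_ddd_table(path=None) -> DddTable:
    """Load the shipped (or a user-supplied) ``atc_code,drug_name,mg_per_ddd`` CSV."""
    if path is None:
        source = resources.files("rxcohort.data").joinpath("ddd_table.csv")
        fh = source.open("r", newline="")
    else:
        fh = open(path, newline="")
    table: dict[str, float] = {}
    with fh:
        for row in csv.DictReader(fh):
            mg = float(row["mg_per_ddd"])
            table[row["atc_code"]] = mg
            table[row["drug_name"].lower()] = mg
    return DddTable(table)


@dataclass(frozen=True)
class DoseResult:
    """A starting or maintenance dose in DDD/day with its validity status."""

    patient_id: str
    atc_code: str
    dose_ddd_per_day: float | None
    kind: str  # starting | maintenance
    status: str  # valid | missing | too_low | too_high

    @property
    def is_valid(self) -> bool:
        return self.status == "valid"


def _effective_units_per_day(record: PrescriptionRecord) -> float | None:
    upd = record.units_per_day
    if upd is None or upd == 0:
        return None
    if (record.formulation == "liquid_concentrate"
            and record.atc_code.startswith(LIQUID_CONCENTRATE_ATCS)):
        return upd / DROPS_PER_ML
    return upd


def days_supply(record: PrescriptionRecord) -> float | None:
    """units_total / effective units-per-day; None when uncomputable.

    Fractional days are kept. For liquid citalopram/escitalopram the recorded
    drops/day are converted to ml/day first.
    """
    upd = _effective_units_per_day(record)
    if upd is None:
        return None
    return record.units_total / upd


def ddd_per_day(record: PrescriptionRecord) -> float | None:
    """total_ddd / days supply; 0.0 for zero-dose entry errors; None if missing.

    A recorded daily dose of 0 units (division by zero) is read as the
    data-entry error it almost always is and yields 0.0, which the
    plausibility filter then flags as too low.
    """
    if record.total_ddd is None:
        return None
    if record.total_ddd == 0:
        return 0.0
    days = days_supply(record)
    if days is None:
        return 0.0 if record.units_per_day == 0 else None
    return record.total_ddd / days


def dose_or_zero(record: PrescriptionRecord) -> float:
    """DDD/day with missing doses set to 0 (the maintenance-scan convention)."""
    dose = ddd_per_day(record)
    return 0.0 if dose is None else dose


def dose_status(dose: float | None, kind: str) -> str:
    limit = MAX_STARTING_DDD if kind == "starting" else MAX_MAINTENANCE_DDD
    if dose is None:
        return "missing"
    if dose <= 0:
        return "too_low"
    if dose > limit:
        return "too_high"
    return "valid"


def starting_dose(index_records: Sequence[PrescriptionRecord],
                  patient_id: str | None = None) -> DoseResult:
    """Starting dose from the same-day index prescription(s) of one drug.

    When several prescriptions for the same drug are filled on the index day,
    the one with the lowest daily dose (in DDD/day, so the rule is comparable
    across tablet strengths) is taken; ties break on lowest units_total, then
    input order. Uncomputable records are ignored unless all are uncomputable,
    in which case the result is missing.
    """
    if not index_records:
        raise ValueError("starting_dose requires at least one index record")
    pid = patient_id or index_records[0].patient_id
    atc = index_records[0].atc_code
    computable = [
        (dose, r.units_total, i)
        for i, r in enumerate(index_records)
        if (dose := ddd_per_day(r)) is not None
    ]
    if not computable:
        return DoseResult(pid, atc, None, "starting", "missing")
    dose = min(computable)[0]
    return DoseResult(pid, atc, dose, "starting", dose_status(dose, "starting"))


def mg_per_day(atc_or_name: str, dose_ddd_per_day: float, ddd_table: DddTable) -> float:
    """Convert DDD/day to mg/day for a drug in the table."""
    if dose_ddd_per_day < 0:
        raise ValueError("dose must be >= 0")
    return dose_ddd_per_day * ddd_table.lookup(atc_or_name)


def ddd_from_mg(atc_or_name: str, mg_daily: float, ddd_table: DddTable) -> float:
    """Convert mg/day to DDD/day; exact inverse of :func:`mg_per_day`."""
    if mg_daily < 0:
        raise ValueError("mg must be >= 0")
    return mg_daily / ddd_table.lookup(atc_or_name)
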