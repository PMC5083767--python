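"""Dispensing data model and the CSV dialect every pipeline stage consumes.

Two tables describe a dataset:

* ``patients.csv`` — ``patient_id, sex, birth_date, db_entry_date``
* ``prescriptions.csv`` — ``patient_id, fill_date, atc_code, units_total,
  units_per_day, total_ddd, formulation, prescriber``

Dates are ISO-8601 calendar dates; all date arithmetic downstream is in whole
days. The empty string encodes a missing ``units_per_day`` / ``total_ddd``
(a real feature of dispensing extracts: data-entry errors with missing or
zero daily doses are common enough that the analysis has explicit plausibility
filters for them) and a missing ``sex``. ``db_entry_date`` is stored per
patient — the first-ever record of any drug in the source database — so the
six-months-of-history inclusion rule can be checked even when those earlier
records are not part of the extract.

``formulation`` and ``prescriber`` are conventions of this dialect (the source
database does not name such columns): the liquid-concentrate dose correction
and the GP/specialist stratification both need them, and inferring either from
free text would be unverifiable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable

from .codes import ATC_PATTERN, is_antidepressant  # noqa: F401  (re-exported)

SEXES = ("F", "M", "missing")
FORMULATIONS = ("solid", "liquid_concentrate", "other")
PRESCRIBERS = ("GP", "specialist", "unknown")

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "db_entry_date"]
PRESCRIPTION_COLUMNS = [
    "patient_id",
    "fill_date",
    "atc_code",
    "units_total",
    "units_per_day",
    "total_ddd",
    "formulation",
    "prescriber",
]


class DatasetError(ValueError):
    """Fatal dataset problem: unreadable file, bad schema, invalid rows."""


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # F | M | missing
    birth_date: date
    db_entry_date: date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise DatasetError("patient_id must be non-empty")
        if self.sex not in SEXES:
            raise DatasetError(f"invalid sex {self.sex!r} for {self.patient_id}")


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    fill_date: date
    atc_code: str
    units_total: float
    units_per_day: float | None  # recorded daily dose in units; drops for liquids
    total_ddd: float | None
    formulation: str = "solid"
    prescriber: str = "unknown"

    def __post_init__(self) -> None:
        if not (isinstance(self.atc_code, str) and ATC_PATTERN.match(self.atc_code)
                and len(self.atc_code) >= 4):
            raise DatasetError(f"invalid ATC code {self.atc_code!r}")
        if not self.units_total > 0:
            raise DatasetError(f"units_total must be > 0, got {self.units_total}")
        if self.units_per_day is not None and self.units_per_day < 0:
            raise DatasetError("units_per_day must be >= 0 or missing")
        if self.total_ddd is not None and self.total_ddd < 0:
            raise DatasetError("total_ddd must be >= 0 or missing")
        if self.formulation not in FORMULATIONS:
            raise DatasetError(f"invalid formulation {self.formulation!r}")
        if self.prescriber not in PRESCRIBERS:
            raise DatasetError(f"invalid prescriber {self.prescriber!r}")
        # normalise numerics to float so write->read round-trips are value- and
        # byte-stable (ints and floats would otherwise print differently)
        object.__setattr__(self, "units_total", float(self.units_total))
        if self.units_per_day is not None:
            object.__setattr__(self, "units_per_day", float(self.units_per_day))
        if self.total_ddd is not None:
            object.__setattr__(self, "total_ddd", float(self.total_ddd))


def _rx_sort_key(r: PrescriptionRecord):
    return (r.patient_id, r.fill_date, r.atc_code, r.units_total,
            -1.0 if r.units_per_day is None else r.units_per_day)


@dataclass
class Dataset:
    """Validated patients + prescriptions; every prescription has a patient."""

    patients: dict[str, Patient]
    prescriptions: list[PrescriptionRecord]
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for r in self.prescriptions:
            if r.patient_id not in self.patients:
                raise DatasetError(
                    f"prescription references unknown patient {r.patient_id!r}"
                )

    def sorted(self) -> "Dataset":
        """Canonical row order: (patient_id, fill_date, atc_code, ...)."""
        return Dataset(
            patients=dict(sorted(self.patients.items())),
            prescriptions=sorted(self.prescriptions, key=_rx_sort_key),
            provenance=self.provenance,
        )

    def prescriptions_for(self, patient_id: str) -> list[PrescriptionRecord]:
        return sorted(
            (r for r in self.prescriptions if r.patient_id == patient_id),
            key=_rx_sort_key,
        )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_prescriptions(self) -> int:
        return len(self.prescriptions)


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_date(value: str, what: str, row: int, errors: list[str]) -> date | None:
    try:
        return date.fromisoformat(value)
    except ValueError:
        errors.append(f"row {row}: invalid {what} {value!r} (expected ISO-8601)")
        return None


def _parse_float(value: str, what: str, row: int, errors: list[str],
                 allow_missing: bool) -> float | None:
    if value == "":
        if allow_missing:
            return None
        errors.append(f"row {row}: missing {what}")
        return None
    try:
        return float(value)
    except ValueError:
        errors.append(f"row {row}: invalid {what} {value!r}")
        return None


def _check_header(header: list[str] | None, expected: list[str], path) -> None:
    if header is None:
        raise DatasetError(f"{path}: empty file, header row required")
    if header != expected:
        unknown = [c for c in header if c not in expected]
        missing = [c for c in expected if c not in header]
        raise DatasetError(
            f"{path}: bad header; unknown columns {unknown}, missing {missing}"
        )


def read_dataset(patients_path, prescriptions_path) -> Dataset:
    """Read and validate the CSV pair.

    Rows failing type validation are reported together, each with its
    1-based data-row number; any failure is fatal. A prescription whose
    ``patient_id`` is absent from the patients table is fatal and names the
    offending id.
    """
    patients_path = Path(patients_path)
    prescriptions_path = Path(prescriptions_path)
    for p in (patients_path, prescriptions_path):
        if not p.exists():
            raise DatasetError(f"missing file: {p}")

    errors: list[str] = []
    patients: dict[str, Patient] = {}
    with open(patients_path, newline="") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), PATIENT_COLUMNS, patients_path)
        for i, row in enumerate(reader, start=1):
            if len(row) != len(PATIENT_COLUMNS):
                errors.append(f"row {i}: expected {len(PATIENT_COLUMNS)} fields")
                continue
            pid, sex, birth, entry = row
            sex = sex or "missing"
            birth_d = _parse_date(birth, "birth_date", i, errors)
            entry_d = _parse_date(entry, "db_entry_date", i, errors)
            if birth_d is None or entry_d is None:
                continue
            if pid in patients:
                errors.append(f"row {i}: duplicate patient_id {pid!r}")
                continue
            try:
                patients[pid] = Patient(pid, sex, birth_d, entry_d)
            except DatasetError as exc:
                errors.append(f"row {i}: {exc}")
    if errors:
        raise DatasetError(f"{patients_path}: " + "; ".join(errors))

    prescriptions: list[PrescriptionRecord] = []
    with open(prescriptions_path, newline="") as fh:
        reader = csv.reader(fh)
        _check_header(next(reader, None), PRESCRIPTION_COLUMNS, prescriptions_path)
        for i, row in enumerate(reader, start=1):
            if len(row) != len(PRESCRIPTION_COLUMNS):
                errors.append(f"row {i}: expected {len(PRESCRIPTION_COLUMNS)} fields")
                continue
            pid, fill, atc, units, upd, ddd, form, presc = row
            fill_d = _parse_date(fill, "fill_date", i, errors)
            units_f = _parse_float(units, "units_total", i, errors, allow_missing=False)
            upd_f = _parse_float(upd, "units_per_day", i, errors, allow_missing=True)
            ddd_f = _parse_float(ddd, "total_ddd", i, errors, allow_missing=True)
            if fill_d is None or units_f is None:
                continue
            if pid not in patients:
                raise DatasetError(
                    f"{prescriptions_path} row {i}: prescription for unknown "
                    f"patient {pid!r}"
                )
            try:
                prescriptions.append(
                    PrescriptionRecord(pid, fill_d, atc, units_f, upd_f, ddd_f,
                                       form or "solid", presc or "unknown")
                )
            except DatasetError as exc:
                errors.append(f"row {i}: {exc}")
    if errors:
        raise DatasetError(f"{prescriptions_path}: " + "; ".join(errors))

    return Dataset(patients, prescriptions,
                   provenance=f"read from {patients_path}, {prescriptions_path}")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_dataset(dataset: Dataset, patients_path, prescriptions_path) -> None:
    """Write the CSV pair in canonical row order.

    Output is re-readable by :func:`read_dataset` with value equality
    (modulo canonical ordering), and write∘read∘write is byte-stable.
    """
    ds = dataset.sorted()
    with open(patients_path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PATIENT_COLUMNS)
        for p in ds.patients.values():
            w.writerow([p.patient_id, "" if p.sex == "missing" else p.sex,
                        p.birth_date.isoformat(), p.db_entry_date.isoformat()])
    with open(prescriptions_path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PRESCRIPTION_COLUMNS)
        for r in ds.prescriptions:
            w.writerow([r.patient_id, r.fill_date.isoformat(), r.atc_code,
                        _fmt(r.units_total), _fmt(r.units_per_day),
                        _fmt(r.total_ddd), r.formulation, r.prescriber])


def dataset_from_records(patients: Iterable[Patient],
                         prescriptions: Iterable[PrescriptionRecord],
                         provenance: str = "") -> Dataset:
    """Convenience constructor from iterables (used by the generator and tests)."""
    return Dataset({p.patient_id: p for p in patients}, list(prescriptions),
                   provenance=provenance)
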