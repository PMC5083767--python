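"""Aggregate tables: first-drug shares, dose distributions, compliance, titration.

All tables are plain pandas DataFrames, deterministic given the input (rows are
sorted before aggregation), with percentages carried at full precision in a
``pct`` column and displayed at one decimal (half-up) in ``pct_display``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import drug_name
from .cohort import CohortEntry
from .doses import DoseResult
from .guidelines import ComplianceResult

OTHERS = "others"


def round_half_up(x: float, digits: int = 1) -> float:
    """Half-up decimal rounding (Python's round() is banker's rounding)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cohort_frame(cohort: Sequence[CohortEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "index_date": e.index_date,
                "atc_code": e.index_atc,
                "drug": drug_name(e.index_atc),
                "age_years": e.age_years,
                "age_group": e.age_group,
                "period": e.period,
                "prescriber": e.prescriber,
            }
            for e in cohort
        ]
    ).sort_values("patient_id", ignore_index=True) if cohort else pd.DataFrame(
        columns=["patient_id", "index_date", "atc_code", "drug", "age_years",
                 "age_group", "period", "prescriber"])


def _top_drugs(frame: pd.DataFrame, top_n: int) -> list[str]:
    counts = frame["atc_code"].value_counts()
    return list(counts.index[:top_n])


def initiation_shares(cohort: Sequence[CohortEntry] | pd.DataFrame,
                      by: str | None = None, top_n: int = 10) -> pd.DataFrame:
    """Percentage of cohort entries starting on each drug, per stratum.

    Strata are calendar period, optionally crossed with ``prescriber`` or
    ``age_group``. The ``top_n`` drugs by overall count are listed
    individually (one shared legend across strata, so strata are comparable);
    the rest are pooled as "others". Percentages within a stratum sum to 100.
    """
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    if frame.empty:
        raise ValueError("initiation_shares requires a non-empty cohort")
    top = _top_drugs(frame, top_n)
    frame = frame.assign(
        drug_pooled=frame["atc_code"].where(frame["atc_code"].isin(top), OTHERS)
    )
    keys = ["period"] + ([by] if by else [])
    rows = []
    drug_order = top + [OTHERS]
    for stratum, grp in frame.groupby(keys, sort=True):
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        total = len(grp)
        counts = grp["drug_pooled"].value_counts()
        for atc in drug_order:
            n = int(counts.get(atc, 0))
            pct = 100.0 * n / total
            rows.append(dict(zip(keys, stratum))
                        | {"atc_code": atc,
                           "drug": OTHERS if atc == OTHERS else drug_name(atc),
                           "n": n, "pct": pct,
                           "pct_display": round_half_up(pct)})
    return pd.DataFrame(rows)


def dose_distribution(doses: Iterable[DoseResult] | pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of valid doses per drug.

    The median convention is the midpoint of the two central order statistics
    for even counts (numpy's linear-interpolation quantiles).
    """
    if isinstance(doses, pd.DataFrame):
        frame = doses
    else:
        frame = pd.DataFrame(
            [{"atc_code": d.atc_code, "dose": d.dose_ddd_per_day}
             for d in doses if d.is_valid]
        )
    if frame.empty:
        return pd.DataFrame(columns=["atc_code", "drug", "count", "min", "q1",
                                     "median", "q3", "max"])
    rows = []
    for atc, grp in frame.groupby("atc_code", sort=True):
        values = np.sort(grp["dose"].to_numpy(dtype=float))
        rows.append({
            "atc_code": atc,
            "drug": drug_name(atc),
            "count": len(values),
            "min": values[0],
            "q1": float(np.percentile(values, 25)),
            "median": float(np.percentile(values, 50)),
            "q3": float(np.percentile(values, 75)),
            "max": values[-1],
        })
    return pd.DataFrame(rows)


def compliance_table(results: Iterable[ComplianceResult] | pd.DataFrame,
                     cohort: Sequence[CohortEntry] | Mapping[str, str] | None = None
                     ) -> pd.DataFrame:
    """Per age group x drug: n and % guideline-compliant, n and % adult dose.

    A Total row per age group sums the covered drugs, so its N is the total
    number of classified prescriptions in that age group. Drugs the ruleset
    does not cover (compliant is None) are omitted.
    """
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        if cohort is None:
            raise ValueError("cohort (or an age_group mapping) is required")
        if not isinstance(cohort, Mapping):
            cohort = {e.patient_id: e.age_group for e in cohort}
        frame = pd.DataFrame(
            [{"patient_id": r.patient_id, "atc_code": r.atc_code,
              "age_group": cohort[r.patient_id],
              "compliant": r.compliant, "adult_dose": r.adult_dose}
             for r in results if r.compliant is not None]
        )
    if frame.empty:
        return pd.DataFrame(columns=["age_group", "atc_code", "drug", "N",
                                     "n_compliant", "pct_compliant",
                                     "n_adult_dose", "pct_adult_dose"])
    rows = []
    for (age_group, atc), grp in frame.groupby(["age_group", "atc_code"], sort=True):
        rows.append(_compliance_row(age_group, atc, drug_name(atc), grp))
    for age_group, grp in frame.groupby("age_group", sort=True):
        rows.append(_compliance_row(age_group, "Total", "Total", grp))
    return pd.DataFrame(rows)


def _compliance_row(age_group: str, atc: str, name: str, grp: pd.DataFrame) -> dict:
    n = len(grp)
    n_comp = int(grp["compliant"].sum())
    n_adult = int(grp["adult_dose"].sum())
    return {
        "age_group": age_group, "atc_code": atc, "drug": name, "N": n,
        "n_compliant": n_comp,
        "pct_compliant": round_half_up(100.0 * n_comp / n),
        "n_adult_dose": n_adult,
        "pct_adult_dose": round_half_up(100.0 * n_adult / n),
    }


def titration_summary(directions: Iterable[str]) -> dict[str, float]:
    """Percentages of patients staying at, raising, or lowering their dose."""
    counts = {"same": 0, "up": 0, "down": 0}
    total = 0
    for d in directions:
        d = getattr(d, "direction", d)
        counts[d] += 1
        total += 1
    if total == 0:
        raise ValueError("titration_summary requires a non-empty input")
    return {k: 100.0 * v / total for k, v in counts.items()}


def demographics_summary(cohort: Sequence[CohortEntry],
                         sex_by_patient: Mapping[str, str] | None = None) -> dict:
    """Counts and percentages of sex, age group, period and prescriber,
    plus mean age at initiation."""
    if not cohort:
        raise ValueError("demographics_summary requires a non-empty cohort")
    frame = cohort_frame(cohort)
    if sex_by_patient is not None:
        frame["sex"] = frame["patient_id"].map(sex_by_patient)
    out: dict = {"n": len(frame), "mean_age": float(frame["age_years"].mean())}
    for column in ("sex", "age_group", "period", "prescriber"):
        if column not in frame:
            continue
        counts = frame[column].value_counts().sort_index()
        out[column] = pd.DataFrame({
            "n": counts,
            "pct": 100.0 * counts / len(frame),
        })
    return out
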