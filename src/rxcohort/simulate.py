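"""Synthetic dispensing-data generator with exported ground truth.

The generator emulates the statistical structure a community-pharmacy
dispensing extract presents to this analysis: per-period drug-choice mixtures
over ~15 antidepressant ATC codes, tablet-strength-quantized starting-dose
distributions, refill chains with gaps, planted exclusion scenarios
(desmopressin co-prescription, prior pain medication, same-day dual starts,
short database history, out-of-range ages), realistic data-entry error rates
(missing or zero daily doses, implausibly high doses), a prescriber mix that
shifts from GP to specialist over calendar time, and patients present in the
database without any antidepressant record.

Every patient carries a ground-truth label — intended inclusion/exclusion
rule, true index drug, true starting-dose level, true maintenance dose and
episode presence, true titration direction — consistent with the emitted
records by construction, so every pipeline stage has a known answer.

Randomness: one ``numpy`` SeedSequence per dataset, spawned into an
independent child stream per patient. Changing one patient's draws, or adding
draws for a new config field, never shifts any other patient's records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (Dataset, Patient, PrescriptionRecord, dataset_from_records,
                 write_dataset)

P1, P2, P3 = "1994-2003", "2004-2009", "2010-2014"

_PERIOD_BOUNDS = {
    P1: (date(1994, 1, 1), date(2003, 12, 31)),
    P2: (date(2004, 1, 1), date(2009, 12, 31)),
    P3: (date(2010, 1, 1), date(2014, 12, 31)),
}

# Per-period first-drug mixtures. Paroxetine dominates early and collapses
# after its suicidality association became prominent; citalopram takes over
# from 2004; fluoxetine rises from ~10% to ~19.7%; escitalopram only exists
# from the 2000s. Probabilities per period sum to 1.
_DRUG_MIXTURE = {
    P1: {
        "N06AB05": 0.24, "N06AB04": 0.10, "N06AB03": 0.10, "N06AA09": 0.14,
        "N06AB06": 0.06, "N06AB08": 0.06, "N06AA02": 0.06, "N06AA04": 0.05,
        "N06AX11": 0.04, "N06AX16": 0.05, "N06AA10": 0.04, "N06AX05": 0.03,
        "N06AX03": 0.03, "N06AB10": 0.00, "N06AX21": 0.00,
    },
    P2: {
        "N06AB04": 0.28, "N06AB05": 0.08, "N06AB03": 0.15, "N06AA09": 0.12,
        "N06AB06": 0.08, "N06AB08": 0.05, "N06AX11": 0.05, "N06AX16": 0.06,
        "N06AB10": 0.04, "N06AA02": 0.03, "N06AA04": 0.02, "N06AA10": 0.02,
        "N06AX05": 0.01, "N06AX03": 0.01, "N06AX21": 0.00,
    },
    P3: {
        "N06AB04": 0.30, "N06AB03": 0.197, "N06AB06": 0.10, "N06AB08": 0.04,
        "N06AB05": 0.04, "N06AA09": 0.10, "N06AB10": 0.06, "N06AX11": 0.04,
        "N06AX16": 0.05, "N06AA02": 0.02, "N06AA04": 0.01, "N06AA10": 0.01,
        "N06AX21": 0.02, "N06AX05": 0.01, "N06AX03": 0.003,
    },
}

# Starting-dose levels (DDD/day) quantized to plausible tablet strengths, and
# their probabilities. E.g. fluoxetine is essentially only available as 20 mg
# (1 DDD) tablets, so low doses are rare; citalopram's oral solution makes
# low, oddly-quantized doses common.
_DOSE_LEVELS = {
    "N06AB03": ((0.25, 0.5, 1.0), (0.065, 0.235, 0.70)),
    "N06AB04": ((0.25, 0.4, 0.5, 1.0), (0.249, 0.10, 0.251, 0.40)),
    "N06AB05": ((0.5, 1.0), (0.35, 0.65)),
    "N06AB06": ((0.5, 1.0, 1.5), (0.25, 0.65, 0.10)),
    "N06AB08": ((0.25, 0.5, 1.0), (0.145, 0.455, 0.40)),
    "N06AB10": ((0.5, 1.0), (0.50, 0.50)),
    "N06AA02": ((0.1, 0.25, 0.5), (0.40, 0.40, 0.20)),
    "N06AA04": ((0.1, 0.25, 0.5), (0.30, 0.40, 0.30)),
    "N06AA09": ((0.1, 0.2, 0.4, 0.8), (0.30, 0.30, 0.25, 0.15)),
    "N06AA10": ((0.15, 0.3, 0.6), (0.40, 0.40, 0.20)),
    "N06AX03": ((0.5, 1.0), (0.60, 0.40)),
    "N06AX05": ((0.17, 0.33), (0.60, 0.40)),
    "N06AX11": ((0.25, 0.5, 1.0), (0.20, 0.50, 0.30)),
    "N06AX16": ((0.375, 0.75, 1.5), (0.25, 0.55, 0.20)),
    "N06AX21": ((0.5, 1.0), (0.50, 0.50)),
}

_PRESCRIBER_PROBS = {
    P1: {"GP": 0.62, "specialist": 0.36, "unknown": 0.02},
    P2: {"GP": 0.45, "specialist": 0.53, "unknown": 0.02},
    P3: {"GP": 0.29, "specialist": 0.69, "unknown": 0.02},
}

_ANALGESIC_ATCS = ("M01AE01", "N02BE01", "N02BA01", "N03AX12")

#: generated prescriptions all carry a 30-day supply (monthly dispensing)
_SUPPLY_DAYS = 30


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset. All rates are per patient."""

    seed: int
    n_patients: int = 1000
    study_start: date = date(1994, 1, 1)
    study_end: date = date(2014, 12, 31)
    period_weights: dict = field(default_factory=lambda: {P1: 0.406, P2: 0.277,
                                                          P3: 0.317})
    sex_probs: dict = field(default_factory=lambda: {"F": 0.59, "M": 0.40,
                                                     "missing": 0.01})
    age_group_probs: dict = field(default_factory=lambda: {"child": 0.11,
                                                           "preteen": 0.19,
                                                           "teen": 0.70})
    drug_mixture: dict = field(default_factory=lambda: {
        p: dict(m) for p, m in _DRUG_MIXTURE.items()})
    dose_levels: dict = field(default_factory=lambda: dict(_DOSE_LEVELS))
    prescriber_probs: dict = field(default_factory=lambda: {
        p: dict(m) for p, m in _PRESCRIBER_PROBS.items()})
    liquid_prob: float = 0.15  # citalopram/escitalopram oral solution share
    # planted patient scenarios
    p_no_antidepressant: float = 0.04
    p_bedwetting: float = 0.02
    p_pain: float = 0.02
    p_same_day_dual: float = 0.002
    p_history_short: float = 0.02
    p_age_out: float = 0.01
    # planted index data-entry errors (among included patients)
    p_dup_same_day: float = 0.03
    p_missing_upd: float = 0.001
    p_zero_upd: float = 0.087
    p_high_dose: float = 0.002
    high_dose_level: float = 5.0
    # refill-chain shape
    p_maintenance: float = 0.53
    refill_count_range: tuple = (2, 4)     # inclusive
    refill_gap_range: tuple = (20, 37)     # inclusive, always covered by grace
    p_lapsed_refill: float = 0.5           # non-maintainers: one late refill
    lapsed_gap_range: tuple = (39, 90)     # beyond the 25% grace of 30 days
    titration_probs: dict = field(default_factory=lambda: {"same": 0.60,
                                                           "up": 0.35,
                                                           "down": 0.05})
    # co-medication noise (never label-changing by construction)
    p_noise_analgesic: float = 0.05
    p_noise_desmopressin: float = 0.01

    def validate(self) -> None:
        def check_mixture(name, probs):
            vals = list(probs.values())
            if any(not (0.0 <= v <= 1.0) for v in vals):
                raise ConfigError(f"{name}: probabilities must be in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities sum to {sum(vals)}, not 1")

        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        check_mixture("period_weights", self.period_weights)
        check_mixture("sex_probs", self.sex_probs)
        check_mixture("age_group_probs", self.age_group_probs)
        check_mixture("titration_probs", self.titration_probs)
        for period, mixture in self.drug_mixture.items():
            check_mixture(f"drug_mixture[{period}]", mixture)
        for period, mixture in self.prescriber_probs.items():
            check_mixture(f"prescriber_probs[{period}]", mixture)
        for atc, (levels, probs) in self.dose_levels.items():
            check_mixture(f"dose_levels[{atc}]", dict(enumerate(probs)))
            if len(levels) != len(probs) or any(not 0 < lv <= 3 for lv in levels):
                raise ConfigError(f"dose_levels[{atc}]: bad levels {levels}")
        scenario = (self.p_no_antidepressant + self.p_bedwetting + self.p_pain
                    + self.p_same_day_dual + self.p_history_short + self.p_age_out)
        if scenario > 1.0:
            raise ConfigError("scenario probabilities exceed 1")
        style = (self.p_dup_same_day + self.p_missing_upd + self.p_zero_upd
                 + self.p_high_dose)
        if style > 1.0:
            raise ConfigError("index-style probabilities exceed 1")


def default_config(seed: int = 0, n_patients: int = 1000,
                   **overrides) -> SimulationConfig:
    """The documented default study conditions; see docs/methods.md."""
    config = replace(SimulationConfig(seed=seed, n_patients=n_patients),
                     **overrides)
    config.validate()
    return config


@dataclass(frozen=True)
class GroundTruthRecord:
    """Planted truth for one patient; empty strings mean 'not applicable'."""

    patient_id: str
    label: str  # included | bedwetting | pain | same_day_dual | history | age
    #         | no_antidepressant
    index_atc: str = ""  # "A|B" for dual starts
    start_dose_level: float | None = None  # planted level before any error
    start_status: str = ""  # valid | missing | too_low | too_high
    has_maintenance: bool | None = None
    maintenance_dose: float | None = None
    titration: str = ""  # same | up | down; "" when undefined


def _categorical(rng: np.random.Generator, probs: dict):
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.array([probs[k] for k in keys]))]


def _rand_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _level_up(levels: tuple, dose: float) -> float:
    higher = [lv for lv in levels if lv > dose + 1e-12]
    return min(higher) if higher else dose * 2.0


def _level_down(levels: tuple, dose: float) -> float:
    lower = [lv for lv in levels if lv < dose - 1e-12]
    return max(lower) if lower else dose / 2.0


class _PatientBuilder:
    """Assembles one patient's records from per-patient random draws."""

    def __init__(self, config: SimulationConfig, pid: str,
                 rng: np.random.Generator):
        self.cfg = config
        self.pid = pid
        self.rng = rng
        self.records: list[PrescriptionRecord] = []

    # -- record emitters ----------------------------------------------------

    def antidepressant_fill(self, fill: date, atc: str, dose: float,
                            prescriber: str, *, liquid: bool = False,
                            style: str = "single") -> None:
        total_ddd: float | None = dose * _SUPPLY_DAYS
        if liquid:
            upd: float | None = 8.0  # drops/day; 8/20 = 0.4 ml/day
            units = _SUPPLY_DAYS * upd / 20.0
            formulation = "liquid_concentrate"
        else:
            upd = 1.0
            units = float(_SUPPLY_DAYS)
            formulation = "solid"
        if style == "missing_upd":
            upd = None
        elif style == "zero_upd":
            upd = 0.0
        self.records.append(PrescriptionRecord(
            self.pid, fill, atc, units, upd, total_ddd, formulation, prescriber))

    def comedication(self, fill: date, atc: str) -> None:
        self.records.append(PrescriptionRecord(
            self.pid, fill, atc, 30.0, 3.0, 10.0, "solid", "GP"))

    # -- refill chains ------------------------------------------------------

    def maintenance_chain(self, index_date: date, atc: str, dose: float,
                          prescriber: str) -> None:
        lo, hi = self.cfg.refill_count_range
        n = int(self.rng.integers(lo, hi + 1))
        t = index_date
        for _ in range(n):
            t = t + timedelta(days=int(self.rng.integers(
                self.cfg.refill_gap_range[0], self.cfg.refill_gap_range[1] + 1)))
            self.antidepressant_fill(t, atc, dose, prescriber)

    def lapsed_refill(self, index_date: date, atc: str, dose: float,
                      prescriber: str) -> None:
        gap = int(self.rng.integers(self.cfg.lapsed_gap_range[0],
                                    self.cfg.lapsed_gap_range[1] + 1))
        self.antidepressant_fill(index_date + timedelta(days=gap), atc, dose,
                                 prescriber)


def simulate(config: SimulationConfig) -> tuple[Dataset, list[GroundTruthRecord]]:
    """Generate a dataset plus per-patient ground truth; reproducible by seed."""
    config.validate()
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_patients)
    patients: list[Patient] = []
    prescriptions: list[PrescriptionRecord] = []
    truth: list[GroundTruthRecord] = []

    age_ranges = {"child": (6.05, 9.95), "preteen": (10.05, 13.95),
                  "teen": (14.05, 17.95)}
    scenario_probs = {
        "no_antidepressant": cfg.p_no_antidepressant,
        "bedwetting": cfg.p_bedwetting,
        "pain": cfg.p_pain,
        "same_day_dual": cfg.p_same_day_dual,
        "history": cfg.p_history_short,
        "age": cfg.p_age_out,
    }
    scenario_probs["included"] = 1.0 - sum(scenario_probs.values())
    style_probs = {
        "dup_same_day": cfg.p_dup_same_day,
        "missing_upd": cfg.p_missing_upd,
        "zero_upd": cfg.p_zero_upd,
        "high_dose": cfg.p_high_dose,
    }
    style_probs["single"] = 1.0 - sum(style_probs.values())

    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:05d}"
        builder = _PatientBuilder(cfg, pid, rng)
        label = _categorical(rng, scenario_probs)
        sex = _categorical(rng, cfg.sex_probs)
        period = _categorical(rng, cfg.period_weights)
        lo, hi = _PERIOD_BOUNDS[period]
        # leave >=200 days of history room at the study start and >=400 days
        # of refill room at the study end (episodes truncate at database exit)
        index_date = _rand_date(rng,
                                max(lo, cfg.study_start + timedelta(days=200)),
                                min(hi, cfg.study_end - timedelta(days=400)))

        if label == "no_antidepressant":
            age = rng.uniform(*age_ranges["teen"])
            birth = index_date - timedelta(days=round(age * 365.25))
            entry = _rand_date(rng, cfg.study_start, index_date)
            patients.append(Patient(pid, sex, birth, entry))
            for _ in range(int(rng.integers(1, 3))):
                builder.comedication(_rand_date(rng, entry, cfg.study_end),
                                     str(rng.choice(_ANALGESIC_ATCS)))
            prescriptions.extend(builder.records)
            truth.append(GroundTruthRecord(pid, label))
            continue

        # age at index
        if label == "age":
            age = rng.uniform(4.1, 5.9) if rng.random() < 0.5 \
                else rng.uniform(18.05, 19.9)
        else:
            age = rng.uniform(*age_ranges[_categorical(rng, cfg.age_group_probs)])
        birth = index_date - timedelta(days=round(age * 365.25))

        # database history
        if label == "history":
            entry = index_date - timedelta(days=int(rng.integers(0, 183)))
        else:
            entry = max(cfg.study_start,
                        index_date - timedelta(days=183 + int(rng.integers(0, 3000))))
        patients.append(Patient(pid, sex, birth, entry))

        prescriber = _categorical(rng, cfg.prescriber_probs[period])
        mixture = cfg.drug_mixture[period]

        # index drug(s)
        if label == "bedwetting":
            atc = str(rng.choice(["N06AA09", "N06AA02"]))
        elif label == "pain":
            atc = str(rng.choice(["N06AA09", "N06AA02", "N06AA04", "N06AA10"]))
        elif label == "same_day_dual":
            keys = [k for k, v in mixture.items() if v > 0]
            p = np.array([mixture[k] for k in keys])
            pair = rng.choice(len(keys), size=2, replace=False, p=p / p.sum())
            atc = f"{keys[pair[0]]}|{keys[pair[1]]}"
        else:
            atc = _categorical(rng, mixture)

        style = _categorical(rng, style_probs) if label == "included" else "single"

        # index prescriptions
        if label == "same_day_dual":
            for code in atc.split("|"):
                levels, probs = cfg.dose_levels[code]
                dose = float(rng.choice(levels, p=np.array(probs)))
                builder.antidepressant_fill(index_date, code, dose, prescriber)
            level = None
        else:
            levels, probs = cfg.dose_levels[atc]
            level = float(rng.choice(levels, p=np.array(probs)))
            liquid = (atc in ("N06AB04", "N06AB10")
                      and rng.random() < cfg.liquid_prob)
            if style == "high_dose":
                builder.antidepressant_fill(index_date, atc,
                                            cfg.high_dose_level, prescriber)
            elif style in ("missing_upd", "zero_upd"):
                builder.antidepressant_fill(index_date, atc, level, prescriber,
                                            liquid=liquid, style=style)
            else:
                builder.antidepressant_fill(index_date, atc, level, prescriber,
                                            liquid=liquid)
                if style == "dup_same_day":
                    builder.antidepressant_fill(
                        index_date, atc, _level_up(levels, level), prescriber)

        start_status = {"single": "valid", "dup_same_day": "valid",
                        "missing_upd": "missing", "zero_upd": "too_low",
                        "high_dose": "too_high"}[style]

        # refill chain (index drug only; dual starts get none)
        has_maintenance: bool | None = None
        maintenance_dose: float | None = None
        titration = ""
        if label != "same_day_dual":
            has_maintenance = bool(rng.random() < cfg.p_maintenance)
            direction = _categorical(rng, cfg.titration_probs)
            if has_maintenance:
                if start_status == "valid":
                    titration = direction
                    if direction == "up":
                        maintenance_dose = _level_up(levels, level)
                    elif direction == "down":
                        maintenance_dose = _level_down(levels, level)
                    else:
                        maintenance_dose = level
                else:
                    maintenance_dose = level  # clean refills after a bad index row
                builder.maintenance_chain(index_date, atc, maintenance_dose,
                                          prescriber)
            elif rng.random() < cfg.p_lapsed_refill:
                builder.lapsed_refill(index_date, atc, level, prescriber)

        # planted exclusion triggers
        if label == "bedwetting":
            builder.comedication(_rand_date(rng, index_date, cfg.study_end),
                                 "H01BA02")
        elif label == "pain":
            for _ in range(int(rng.integers(2, 4))):
                offset = int(rng.integers(1, 184))
                builder.comedication(index_date - timedelta(days=offset),
                                     str(rng.choice(_ANALGESIC_ATCS)))

        # co-medication noise, scoped so it can never flip a label
        is_tca_start = atc.split("|")[0].startswith("N06AA")
        if label in ("included", "history", "age"):
            if not atc.startswith(("N06AA09", "N06AA02")) \
                    and rng.random() < cfg.p_noise_desmopressin:
                builder.comedication(_rand_date(rng, index_date, cfg.study_end),
                                     "H01BA02")
            if rng.random() < cfg.p_noise_analgesic:
                if is_tca_start:
                    when = _rand_date(rng, index_date + timedelta(days=1),
                                      cfg.study_end)
                else:
                    when = _rand_date(rng, entry, cfg.study_end)
                builder.comedication(when, str(rng.choice(_ANALGESIC_ATCS)))

        prescriptions.extend(builder.records)
        if label == "included":
            truth.append(GroundTruthRecord(
                pid, label, index_atc=atc, start_dose_level=level,
                start_status=start_status, has_maintenance=has_maintenance,
                maintenance_dose=maintenance_dose if has_maintenance else None,
                titration=titration if has_maintenance else ""))
        else:
            truth.append(GroundTruthRecord(pid, label, index_atc=atc))

    dataset = dataset_from_records(
        patients, prescriptions,
        provenance=f"rxcohort.simulate seed={cfg.seed} n={cfg.n_patients}")
    return dataset.sorted(), truth


def ground_truth_frame(truth: list[GroundTruthRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([{
        "patient_id": t.patient_id,
        "label": t.label,
        "index_atc": t.index_atc,
        "start_dose_level": "" if t.start_dose_level is None
        else repr(t.start_dose_level),
        "start_status": t.start_status,
        "has_maintenance": "" if t.has_maintenance is None
        else str(t.has_maintenance),
        "maintenance_dose": "" if t.maintenance_dose is None
        else repr(t.maintenance_dose),
        "titration": t.titration,
    } for t in truth])
    return frame.sort_values("patient_id", ignore_index=True)


def write_fixture(dataset: Dataset, truth: list[GroundTruthRecord],
                  out_dir) -> None:
    """Write the CSV pair plus a ground-truth TSV into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, out / "patients.csv", out / "prescriptions.csv")
    ground_truth_frame(truth).to_csv(out / "ground_truth.tsv", sep="\t",
                                     index=False, lineterminator="\n")
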