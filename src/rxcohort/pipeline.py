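"""End-to-end orchestration: dataset → cohort → doses → episodes → compliance.

Thin glue over the stage modules; each stage remains independently usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohort import (CohortConfig, CohortEntry, DEFAULT_CONFIG, ExclusionRecord,
                     build_cohort)
from .doses import DoseResult, starting_dose
from .guidelines import ComplianceResult, classify_maintenance, classify_start, default_rules
from .io import Dataset
from .maintenance import (MaintenanceEpisode, TitrationResult, classify_titration,
                          detect_episodes, select_primary_episode)
from . import report


@dataclass
class PipelineResult:
    cohort: list[CohortEntry]
    exclusions: list[ExclusionRecord]
    start_doses: dict[str, DoseResult]
    primary_episodes: dict[str, MaintenanceEpisode]  # patients with >=1 episode
    titrations: dict[str, TitrationResult]  # valid start + episode only
    start_compliance: dict[str, ComplianceResult]  # valid starts only
    maint_compliance: dict[str, ComplianceResult]
    ruleset: str = "dutch_lenient"
    _entry_by_id: dict = field(default_factory=dict, repr=False)

    # convenience views ------------------------------------------------------

    def start_dose_frame(self) -> pd.DataFrame:
        rows = []
        for pid, dose in sorted(self.start_doses.items()):
            entry = self._entry_by_id[pid]
            rows.append({
                "patient_id": pid, "atc_code": dose.atc_code,
                "dose": dose.dose_ddd_per_day, "status": dose.status,
                "age_group": entry.age_group, "period": entry.period,
                "prescriber": entry.prescriber,
            })
        return pd.DataFrame(rows)

    def titration_summary(self) -> dict[str, float]:
        return report.titration_summary(self.titrations.values())

    def compliance_table(self) -> pd.DataFrame:
        ages = {e.patient_id: e.age_group for e in self.cohort}
        return report.compliance_table(self.start_compliance.values(), ages)


def run_pipeline(dataset: Dataset, config: CohortConfig = DEFAULT_CONFIG,
                 ruleset: str = "dutch_lenient") -> PipelineResult:
    """Run every analysis stage on a validated dataset."""
    rules = default_rules(ruleset)
    cohort, exclusions = build_cohort(dataset, config)
    result = PipelineResult(cohort=cohort, exclusions=exclusions,
                            start_doses={}, primary_episodes={}, titrations={},
                            start_compliance={}, maint_compliance={},
                            ruleset=ruleset,
                            _entry_by_id={e.patient_id: e for e in cohort})
    for entry in cohort:
        pid = entry.patient_id
        dose = starting_dose(list(entry.index_records), pid)
        result.start_doses[pid] = dose
        if dose.is_valid:
            result.start_compliance[pid] = classify_start(
                dose, entry.age_years, ruleset, rules)

        drug_fills = [r for r in dataset.prescriptions_for(pid)
                      if r.atc_code == entry.index_atc
                      and r.fill_date >= entry.index_date]
        episode = select_primary_episode(detect_episodes(drug_fills))
        if episode is not None:
            result.primary_episodes[pid] = episode
            result.maint_compliance[pid] = classify_maintenance(
                episode, entry.age_years, ruleset, rules)
            if dose.is_valid:
                result.titrations[pid] = classify_titration(dose, episode)
    return result
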