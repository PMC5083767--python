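"""Inclusion criteria, exclusion filters, age bands and calendar periods."""

from datetime import date, timedelta

import pytest

import rxcohort as rx
from rxcohort.cohort import apply_inclusion

from conftest import make_patient, make_rx


class TestAgeGroups:
    @pytest.mark.parametrize("age,group", [
        (6.0, "child"), (9.99, "child"),
        (10.0, "preteen"), (13.0, "preteen"), (13.9, "preteen"),
        (14.0, "teen"), (17.9, "teen"),
    ])
    def test_bands(self, age, group):
        assert rx.assign_age_group(age) == group

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rx.assign_age_group(5.2)
        with pytest.raises(ValueError):
            rx.assign_age_group(18.0)


class TestPeriods:
    @pytest.mark.parametrize("day,period", [
        (date(1994, 1, 1), "1994-2003"), (date(2003, 12, 31), "1994-2003"),
        (date(2004, 1, 1), "2004-2009"), (date(2009, 12, 31), "2004-2009"),
        (date(2010, 1, 1), "2010-2014"), (date(2014, 6, 1), "2010-2014"),
    ])
    def test_boundaries_by_calendar_year(self, day, period):
        assert rx.assign_period(day) == period

    def test_outside_study_raises(self):
        with pytest.raises(ValueError):
            rx.assign_period(date(1993, 12, 31))


class TestIndexEvent:
    def test_earliest_antidepressant_wins(self):
        ds = rx.dataset_from_records(
            [make_patient()],
            [make_rx(fill=date(2011, 1, 1), atc="N06AB04"),
             make_rx(fill=date(2010, 3, 1), atc="N06AB03")])
        index_date, atcs = rx.find_index_event(ds, "P1")
        assert index_date == date(2010, 3, 1)
        assert atcs == {"N06AB03"}

    def test_no_antidepressant_returns_none(self):
        ds = rx.dataset_from_records([make_patient()],
                                     [make_rx(atc="N02BE01")])
        assert rx.find_index_event(ds, "P1") is None

    def test_duplicate_same_drug_gives_single_element_set(self):
        fills = [make_rx(), make_rx(units=60.0)]
        ds = rx.dataset_from_records([make_patient()], fills)
        # brute-force reference: earliest date over all antidepressant fills
        expected_date = min(r.fill_date for r in fills)
        index_date, atcs = rx.find_index_event(ds, "P1")
        assert index_date == expected_date
        assert atcs == {"N06AB03"}
        assert len(atcs) == 1


class TestInclusion:
    def _dataset(self, birth=date(2000, 1, 1), entry=date(2009, 1, 1),
                 fills=None):
        fills = fills or [make_rx()]
        return rx.dataset_from_records([make_patient(birth=birth, entry=entry)],
                                       fills)

    def test_clean_starter_included_with_group_and_period(self):
        ds = self._dataset()
        entry = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        assert isinstance(entry, rx.CohortEntry)
        assert entry.age_group == "preteen"  # 10.2 years old
        assert entry.period == "2010-2014"
        assert entry.index_atc == "N06AB03"

    def test_short_history_excluded(self):
        ds = self._dataset(entry=date(2010, 3, 1) - timedelta(days=100))
        result = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        assert result == rx.ExclusionRecord("P1", "history", "100 days of history")

    def test_exactly_183_days_is_enough(self):
        ds = self._dataset(entry=date(2010, 3, 1) - timedelta(days=183))
        result = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        assert isinstance(result, rx.CohortEntry)

    @pytest.mark.parametrize("birth", [date(2005, 1, 1), date(1991, 1, 1)])
    def test_age_out_of_range_excluded(self, birth):
        ds = self._dataset(birth=birth, entry=date(1995, 1, 1))
        result = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        assert result.rule == "age"

    def test_same_day_dual_start_excluded(self):
        ds = self._dataset(fills=[make_rx(), make_rx(atc="N06AB04")])
        result = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        assert result.rule == "same_day_dual"

    def test_index_outside_window_excluded(self):
        ds = self._dataset(birth=date(1980, 1, 1), entry=date(1990, 1, 1),
                           fills=[make_rx(fill=date(1993, 6, 1))])
        result = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        assert result == rx.ExclusionRecord("P1", "history", "outside window")


class TestBedwettingFilter:
    def _entry(self, ds):
        return apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))

    def test_amitriptyline_with_desmopressin_years_later_excluded(self):
        ds = rx.dataset_from_records(
            [make_patient()],
            [make_rx(atc="N06AA09"),
             make_rx(fill=date(2012, 3, 1), atc="H01BA02")])
        assert rx.exclude_bedwetting(ds, self._entry(ds)).rule == "bedwetting"

    def test_rule_scoped_to_amitriptyline_and_imipramine(self):
        ds = rx.dataset_from_records(
            [make_patient()],
            [make_rx(atc="N06AB03"),
             make_rx(fill=date(2012, 3, 1), atc="H01BA02")])
        assert isinstance(rx.exclude_bedwetting(ds, self._entry(ds)),
                          rx.CohortEntry)

    def test_no_desmopressin_keeps(self):
        ds = rx.dataset_from_records([make_patient()],
                                     [make_rx(atc="N06AA09")])
        assert isinstance(rx.exclude_bedwetting(ds, self._entry(ds)),
                          rx.CohortEntry)


class TestPainFilter:
    def _dataset(self, index_atc="N06AA09", pain_offsets=(), pain_atcs=None):
        pain_atcs = pain_atcs or ["M01AE01"] * len(pain_offsets)
        fills = [make_rx(atc=index_atc)]
        for off, atc in zip(pain_offsets, pain_atcs):
            fills.append(make_rx(fill=date(2010, 3, 1) - timedelta(days=off),
                                 atc=atc, ddd=10.0))
        return rx.dataset_from_records([make_patient()], fills)

    def _apply(self, ds):
        entry = apply_inclusion(ds, "P1", rx.find_index_event(ds, "P1"))
        return rx.exclude_pain(ds, entry)

    def test_two_analgesics_before_tca_start_excluded(self):
        ds = self._dataset(pain_offsets=(30, 10),
                           pain_atcs=["M01AE01", "N02BE01"])
        assert self._apply(ds).rule == "pain"

    def test_single_analgesic_keeps(self):
        ds = self._dataset(pain_offsets=(30,))
        assert isinstance(self._apply(ds), rx.CohortEntry)

    def test_rule_scoped_to_tricyclics(self):
        ds = self._dataset(index_atc="N06AB03",
                           pain_offsets=(30, 10, 20, 40, 50))
        assert isinstance(self._apply(ds), rx.CohortEntry)

    def test_same_day_analgesics_not_counted(self):
        ds = self._dataset(pain_offsets=(0, 0))
        assert isinstance(self._apply(ds), rx.CohortEntry)

    def test_gabapentin_and_pregabalin_count(self):
        ds = self._dataset(pain_offsets=(30, 10),
                           pain_atcs=["N03AX12", "N03AX16"])
        assert self._apply(ds).rule == "pain"

    def test_window_boundary_183_days(self):
        ds = self._dataset(pain_offsets=(183, 184))
        assert isinstance(self._apply(ds), rx.CohortEntry)  # only one inside


class TestBuildCohort:
    def test_empty_dataset_gives_empty_outputs(self):
        ds = rx.dataset_from_records([make_patient()], [make_rx(atc="N02BE01")])
        assert rx.build_cohort(ds) == ([], [])

    def test_partition_property(self, sim_default):
        _, dataset, _ = sim_default
        entries, exclusions = rx.build_cohort(dataset)
        with_ad = {r.patient_id for r in dataset.prescriptions
                   if rx.is_antidepressant(r.atc_code)}
        assert len(entries) + len(exclusions) == len(with_ad)
        assert {e.patient_id for e in entries}.isdisjoint(
            {e.patient_id for e in exclusions})

    def test_order_independence(self, tiny_dataset):
        shuffled = rx.dataset_from_records(
            tiny_dataset.patients.values(),
            list(reversed(tiny_dataset.prescriptions)))
        assert rx.build_cohort(shuffled) == rx.build_cohort(tiny_dataset)
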