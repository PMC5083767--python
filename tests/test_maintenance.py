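"""Refill-chain episode detection against a brute-force oracle, and titration."""

from datetime import date, timedelta

import numpy as np
import pytest

import rxcohort as rx
from rxcohort.doses import days_supply, dose_or_zero
from rxcohort.maintenance import covers_next

from conftest import make_rx

DAY0 = date(2010, 3, 1)


def fill(day, dose, days=30.0, pid="P1", atc="N06AB03"):
    """A dispensing `days` long at `dose` DDD/day, filled `day` days after DAY0."""
    return make_rx(pid, DAY0 + timedelta(days=day), atc, units=days, upd=1.0,
                   ddd=dose * days)


class TestCoversNext:
    def test_gap_within_grace(self):
        assert covers_next(fill(0, 1.0), fill(37, 1.0))  # 37 <= 30 * 1.25

    def test_gap_beyond_grace(self):
        assert not covers_next(fill(0, 1.0), fill(38, 1.0))

    def test_same_day_is_covered(self):
        assert covers_next(fill(0, 1.0), fill(0, 1.0))


class TestDetectEpisodes:
    def test_two_overlapping_same_dose_fills(self):
        eps = rx.detect_episodes([fill(0, 1.0), fill(25, 1.0)])
        assert len(eps) == 1
        ep = eps[0]
        assert (ep.n_prescriptions, ep.total_days_supply,
                ep.dose_ddd_per_day) == (2, 60.0, 1.0)
        assert ep.duration_days == 55.0

    def test_under_60_days_supply_is_no_episode(self):
        assert rx.detect_episodes([fill(0, 1.0, days=25.0),
                                   fill(20, 1.0, days=25.0)]) == []

    def test_dose_change_splits_runs(self):
        eps = rx.detect_episodes([fill(0, 1.0, 40.0), fill(30, 1.0, 40.0),
                                  fill(60, 0.5, 40.0), fill(90, 0.5, 40.0)])
        assert [e.dose_ddd_per_day for e in eps] == [1.0, 0.5]

    def test_zero_dose_runs_dropped(self):
        records = [make_rx(upd=0.0), make_rx(fill=DAY0 + timedelta(days=1),
                                             upd=0.0)]
        assert rx.detect_episodes(records) == []

    def test_dose_above_four_dropped(self):
        assert rx.detect_episodes([fill(0, 4.5), fill(25, 4.5)]) == []

    def test_missing_dose_set_to_zero_breaks_chain(self):
        records = [fill(0, 1.0), make_rx(fill=DAY0 + timedelta(days=25),
                                         ddd=None), fill(50, 1.0)]
        # the missing-dose fill reads as 0 DDD/day and splits the 1.0 chain
        assert rx.detect_episodes(records) == []


def _sorted_rows(records):
    return sorted(records, key=lambda r: (r.fill_date, dose_or_zero(r),
                                          r.units_total))


def brute_force_spans(records):
    """Independent oracle: enumerate every contiguous subsequence of the
    canonically sorted fills and keep the maximal qualifying ones."""
    rows = _sorted_rows(records)
    qualifying = []
    for i in range(len(rows)):
        for j in range(i + 2, len(rows) + 1):
            seg = rows[i:j]
            doses = [dose_or_zero(r) for r in seg]
            if max(doses) - min(doses) > 1e-9:
                continue
            if not all(covers_next(a, b) for a, b in zip(seg, seg[1:])):
                continue
            if sum(days_supply(r) or 0.0 for r in seg) < 60.0:
                continue
            if not (0.0 < doses[0] <= 4.0):
                continue
            qualifying.append((i, j))
    return [(i, j) for (i, j) in qualifying
            if not any((a <= i and j <= b and (a, b) != (i, j))
                       for (a, b) in qualifying)]


def brute_force_signatures(records):
    rows = _sorted_rows(records)
    out = []
    for i, j in brute_force_spans(records):
        seg = rows[i:j]
        out.append((
            round(dose_or_zero(seg[0]), 9),
            seg[0].fill_date,
            j - i,
            round(sum(days_supply(r) or 0.0 for r in seg), 6),
        ))
    return sorted(out)


def _signatures(episodes):
    return sorted((round(ep.dose_ddd_per_day, 9), ep.start_date,
                   ep.n_prescriptions, round(ep.total_days_supply, 6))
                  for ep in episodes)


class TestOracleEquivalence:
    def test_randomized_instances_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            day, records = 0, []
            for _ in range(n):
                day += int(rng.integers(0, 50))
                dose = float(rng.choice([0.0, 0.5, 1.0]))
                days = float(rng.choice([20.0, 30.0]))
                records.append(fill(day, dose, days))
            detected = rx.detect_episodes(records)
            assert _signatures(detected) == brute_force_signatures(records), \
                records

    def test_oracle_spans_never_overlap(self):
        # each prescription belongs to at most one maximal same-dose run
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            day, records = 0, []
            for _ in range(n):
                day += int(rng.integers(0, 40))
                records.append(fill(day, float(rng.choice([0.5, 1.0])), 30.0))
            spans = sorted(brute_force_spans(records))
            assert _signatures(rx.detect_episodes(records)) == \
                brute_force_signatures(records)
            for (a, b), (c, d) in zip(spans, spans[1:]):
                assert b <= c


class TestPrimaryEpisode:
    def _episode(self, supply, dose, start=DAY0):
        return rx.MaintenanceEpisode("P1", "N06AB03", dose, start, 2, supply,
                                     supply)

    def test_longest_duration_wins(self):
        eps = [self._episode(90.0, 0.5), self._episode(60.0, 1.0)]
        assert rx.select_primary_episode(eps).total_days_supply == 90.0

    def test_highest_dose_breaks_duration_tie(self):
        eps = [self._episode(60.0, 0.5), self._episode(60.0, 1.0)]
        assert rx.select_primary_episode(eps).dose_ddd_per_day == 1.0

    def test_earliest_start_breaks_remaining_tie(self):
        eps = [self._episode(60.0, 1.0, DAY0 + timedelta(days=100)),
               self._episode(60.0, 1.0, DAY0)]
        assert rx.select_primary_episode(eps).start_date == DAY0

    def test_empty_gives_none(self):
        assert rx.select_primary_episode([]) is None


class TestTitration:
    def _start(self, dose):
        return rx.DoseResult("P1", "N06AB03", dose, "starting", "valid")

    @pytest.mark.parametrize("start,maint,direction", [
        (0.5, 1.0, "up"), (1.0, 1.0, "same"), (1.0, 0.5, "down"),
    ])
    def test_directions(self, start, maint, direction):
        ep = rx.MaintenanceEpisode("P1", "N06AB03", maint, DAY0, 2, 60.0, 60.0)
        assert rx.classify_titration(self._start(start), ep).direction == direction

    def test_invalid_start_rejected(self):
        bad = rx.DoseResult("P1", "N06AB03", 0.0, "starting", "too_low")
        ep = rx.MaintenanceEpisode("P1", "N06AB03", 1.0, DAY0, 2, 60.0, 60.0)
        with pytest.raises(ValueError):
            rx.classify_titration(bad, ep)
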