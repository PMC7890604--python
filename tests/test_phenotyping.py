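import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxlatency.cdm_io import EncounterSetting
from dxlatency.phenotyping import (
    ComputedDiagnosis,
    Condition,
    ConditionSpec,
    DailyObservation,
    SignalSeries,
    aggregate_daily,
    compute_diagnosis,
    detect_signals,
    is_signal,
)

from conftest import D, day, lab, vital


def brute_force_two_signal(dates, sep=30):
    """Oracle: enumerate all ordered pairs; second signal is the minimum
    second element over qualifying pairs, first signal the series minimum."""
    qualifying = [d for d in dates for d0 in dates if d0 < d and (d - d0).days >= sep]
    if not qualifying:
        return None
    return min(dates), min(qualifying)


def series(offsets, pid="p1", cond=Condition.DM):
    return SignalSeries(pid, cond, tuple(day(o) for o in sorted(offsets)))


class TestAggregateDaily:
    def test_htn_independent_minima_not_a_signal(self, htn_spec):
        vitals = [vital(sys=150, dia=85), vital(sys=135, dia=95)]
        daily = aggregate_daily(vitals, [], htn_spec)
        assert daily == [
            DailyObservation("p1", D(2015, 1, 1), Condition.HTN, systolic=135, diastolic=85)
        ]
        assert not is_signal(daily[0], htn_spec)

    def test_dm_same_day_minimum_not_a_signal(self, dm_spec):
        labs = [lab(value=6.4), lab(value=7.0)]
        daily = aggregate_daily([], labs, dm_spec)
        assert daily[0].value == 6.4
        assert not is_signal(daily[0], dm_spec)

    def test_inpatient_bp_excluded(self, htn_spec):
        vitals = [vital(sys=180, dia=110, setting=EncounterSetting.INPATIENT)]
        assert aggregate_daily(vitals, [], htn_spec) == []

    def test_non_matching_lab_code_ignored(self, dm_spec):
        assert aggregate_daily([], [lab(code="13457-7", value=200)], dm_spec) == []

    def test_null_values_ignored(self, htn_spec):
        vitals = [vital(sys=None, dia=None)]
        # record invalid at construction level is impossible; both-None rows skipped
        assert aggregate_daily(vitals, [], htn_spec) == []

    def test_permutation_invariance(self, htn_spec):
        vitals = [
            vital(sys=150, dia=85),
            vital(sys=135, dia=95),
            vital("p2", D(2015, 2, 1), 160, 100),
            vital(date=D(2015, 1, 2), sys=141, dia=70),
        ]
        fwd = aggregate_daily(vitals, [], htn_spec)
        rev = aggregate_daily(list(reversed(vitals)), [], htn_spec)
        assert fwd == rev

    def test_one_observation_per_patient_day(self, hld_spec):
        labs = [lab(code="13457-7", value=v) for v in (140, 120, 131)]
        daily = aggregate_daily([], labs, hld_spec)
        assert len(daily) == 1 and daily[0].value == 120


class TestDetectSignals:
    @pytest.mark.parametrize(
        "sys_v,dia_v,expected",
        [(142, 80, True), (120, 90, True), (140, 90, True), (139.9, 89.9, False)],
    )
    def test_htn_threshold_inclusive(self, htn_spec, sys_v, dia_v, expected):
        obs = DailyObservation("p1", D(2015, 1, 1), Condition.HTN, systolic=sys_v, diastolic=dia_v)
        assert is_signal(obs, htn_spec) is expected

    def test_ldl_below_threshold_not_signal(self, hld_spec):
        obs = DailyObservation("p1", D(2015, 1, 1), Condition.HLD, value=129.9)
        assert not is_signal(obs, hld_spec)
        assert is_signal(DailyObservation("p1", D(2015, 1, 1), Condition.HLD, value=130.0), hld_spec)

    def test_series_sorted_unique(self, dm_spec):
        daily = [
            DailyObservation("p1", day(o), Condition.DM, value=7.0) for o in (40, 0, 10)
        ]
        out = detect_signals(daily, dm_spec)
        assert out["p1"].dates == (day(0), day(10), day(40))


class TestComputeDiagnosis:
    def test_29_days_apart_none(self, dm_spec):
        assert compute_diagnosis(series([0, 29]), dm_spec) is None

    def test_30_days_apart_diagnosis(self, dm_spec):
        cd = compute_diagnosis(series([0, 30]), dm_spec)
        assert cd == ComputedDiagnosis("p1", Condition.DM, day(0), day(30))

    def test_intermediate_signal_skipped(self, dm_spec):
        # oracle-derived: pairs (0,40) and (10,40) qualify; earliest second = 40
        cd = compute_diagnosis(series([0, 10, 40]), dm_spec)
        assert (cd.first_signal_date, cd.second_signal_date) == (day(0), day(40))
        assert brute_force_two_signal([day(o) for o in (0, 10, 40)]) == (day(0), day(40))

    def test_earliest_qualifying_pair_wins(self, dm_spec):
        # oracle-derived: (0,39) qualifies before 45
        cd = compute_diagnosis(series([0, 10, 39, 45]), dm_spec)
        assert (cd.first_signal_date, cd.second_signal_date) == (day(0), day(39))
        assert brute_force_two_signal([day(o) for o in (0, 10, 39, 45)]) == (day(0), day(39))

    def test_single_signal_none(self, dm_spec):
        assert compute_diagnosis(series([5]), dm_spec) is None
        assert compute_diagnosis(SignalSeries("p1", Condition.DM, ()), dm_spec) is None

    @given(st.sets(st.integers(0, 400), max_size=20))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, offsets):
        spec = ConditionSpec(Condition.DM, lab_threshold=6.5, lab_codes=frozenset({"4548-4"}))
        s = series(offsets)
        got = compute_diagnosis(s, spec)
        expected = brute_force_two_signal(list(s.dates))
        if expected is None:
            assert got is None
        else:
            assert (got.first_signal_date, got.second_signal_date) == expected

    @given(st.sets(st.integers(0, 300), min_size=2, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_monotonic_under_later_signals(self, offsets):
        spec = ConditionSpec(Condition.DM, lab_threshold=6.5, lab_codes=frozenset({"4548-4"}))
        base = compute_diagnosis(series(offsets), spec)
        if base is None:
            return
        later = max(offsets) + 50
        extended = compute_diagnosis(series(set(offsets) | {later}), spec)
        assert (extended.first_signal_date, extended.second_signal_date) == (
            base.first_signal_date, base.second_signal_date,
        )

    def test_custom_separation(self):
        spec = ConditionSpec(Condition.DM, lab_threshold=6.5,
                             lab_codes=frozenset({"4548-4"}), min_separation_days=0)
        cd = compute_diagnosis(series([3, 4]), spec)
        assert cd.second_signal_date == day(4)


class TestSignalSeriesInvariant:
    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            SignalSeries("p1", Condition.DM, (day(5), day(1)))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            SignalSeries("p1", Condition.DM, (day(1), day(1)))
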