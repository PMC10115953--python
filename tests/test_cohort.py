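import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajmine import cohort as ch
from trajmine.config import RunConfig
from trajmine.data_model import DiagnosisRecord, PatientRecord, PrescriptionRecord

IDX = dt.date(2015, 3, 1)


def rx(day_or_date, drug, supply=30, pid="p1"):
    date = IDX + dt.timedelta(days=day_or_date) if isinstance(day_or_date, int) else day_or_date
    return PrescriptionRecord(pid, date, drug, supply)


def dx(day, code, pid="p1"):
    return DiagnosisRecord(pid, IDX + dt.timedelta(days=day), code)


class TestIndexPrescription:
    def test_single_clean_dispense_is_index(self, class_map):
        info = ch.find_index_prescription([rx(dt.date(2015, 3, 1), "sertraline")], class_map, 2015)
        assert info.index_date == dt.date(2015, 3, 1)
        assert info.index_class == "SSRI"

    def test_washout_violation_yields_none(self, class_map):
        rxs = [rx(dt.date(2014, 9, 1), "sertraline"), rx(dt.date(2015, 3, 1), "sertraline")]
        assert ch.find_index_prescription(rxs, class_map, 2015) is None

    def test_old_use_outside_washout_is_ignored(self, class_map):
        rxs = [rx(dt.date(2013, 9, 1), "sertraline"), rx(dt.date(2015, 3, 1), "venlafaxine")]
        info = ch.find_index_prescription(rxs, class_map, 2015)
        assert info is not None and info.index_class == "SNRI"

    def test_antipsychotic_only_gives_no_index(self, class_map):
        assert ch.find_index_prescription([rx(dt.date(2015, 3, 1), "quetiapine")],
                                          class_map, 2015) is None

    def test_dispense_outside_study_year_ignored(self, class_map):
        assert ch.find_index_prescription([rx(dt.date(2016, 3, 1), "sertraline")],
                                          class_map, 2015) is None


def _patient(age=40, ect=False):
    return PatientRecord("p1", IDX - dt.timedelta(days=round(age * 365.25) + 100), "female", ect)


def _index(class_map):
    return ch.find_index_prescription([rx(0, "sertraline")], class_map, 2015)


class TestEligibility:
    def base_dx(self):
        return [dx(0, "F32.1")]

    @pytest.mark.parametrize("code", ["F20.0", "F30.1", "F31.2", "F06.7", "F00.0"])
    def test_comorbid_codes_excluded_even_in_followup(self, class_map, code):
        res = ch.apply_eligibility(
            _patient(), _index(class_map), self.base_dx() + [dx(200, code)],
            [rx(0, "sertraline")], class_map,
        )
        assert res.exclusion_reason == "comorbid_dx"

    def test_baseline_ect_excluded(self, class_map):
        res = ch.apply_eligibility(_patient(ect=True), _index(class_map), self.base_dx(),
                                   [rx(0, "sertraline")], class_map)
        assert res.exclusion_reason == "ect_baseline"

    @pytest.mark.parametrize("age,reason", [(17, "age"), (66, "age"), (18, "none"), (65, "none")])
    def test_age_bounds_in_completed_years(self, class_map, age, reason):
        res = ch.apply_eligibility(_patient(age=age), _index(class_map), self.base_dx(),
                                   [rx(0, "sertraline")], class_map)
        assert res.exclusion_reason == reason

    def test_two_ads_on_index_date_excluded(self, class_map):
        res = ch.apply_eligibility(
            _patient(), _index(class_map), self.base_dx(),
            [rx(0, "sertraline"), rx(0, "venlafaxine")], class_map,
        )
        assert res.exclusion_reason == "multi_ad_index"

    def test_ad_plus_antipsychotic_on_index_is_monotherapy(self, class_map):
        res = ch.apply_eligibility(
            _patient(), _index(class_map), self.base_dx(),
            [rx(0, "sertraline"), rx(0, "quetiapine")], class_map,
        )
        assert res.eligible

    def test_missing_mdd_diagnosis_excluded(self, class_map):
        res = ch.apply_eligibility(_patient(), _index(class_map), [],
                                   [rx(0, "sertraline")], class_map)
        assert res.exclusion_reason == "no_mdd_dx"

    def test_no_index_is_no_ad(self, class_map):
        res = ch.apply_eligibility(_patient(), None, self.base_dx(), [], class_map)
        assert res.exclusion_reason == "no_ad"

    def test_first_failing_rule_wins(self, class_map):
        # comorbid dx plus bad age plus ECT: comorbid is checked first
        res = ch.apply_eligibility(
            _patient(age=17, ect=True), _index(class_map),
            self.base_dx() + [dx(10, "F20.0")], [rx(0, "sertraline")], class_map,
        )
        assert res.exclusion_reason == "comorbid_dx" and res.applied_order == 2


class TestEpisodeEnd:
    def test_single_supply_ends_at_supply_end(self, class_map):
        w = ch.determine_episode_end([rx(0, "sertraline", 35)], [], IDX, class_map)
        assert w.end_day == 35 and w.episode_ended

    def test_sub_120_gap_is_bridged(self, class_map):
        w = ch.determine_episode_end(
            [rx(0, "sertraline", 30), rx(129, "sertraline", 30)], [], IDX, class_map
        )
        assert w.end_day == 159 and w.episode_ended

    def test_diagnosis_bridges_two_gaps(self, class_map):
        # supply ends day 30; F32 visit day 100; refill day 140: both gaps < 120
        w = ch.determine_episode_end(
            [rx(0, "sertraline", 30), rx(140, "sertraline", 30)],
            [dx(100, "F32.9")], IDX, class_map,
        )
        assert w.end_day == 170 and w.episode_ended

    def test_gap_of_120_or_more_ends_episode(self, class_map):
        w = ch.determine_episode_end(
            [rx(0, "sertraline", 30), rx(150, "sertraline", 30)], [], IDX, class_map
        )
        assert w.end_day == 30

    def test_end_day_capped_at_365(self, class_map):
        rxs = [rx(d, "sertraline", 30) for d in range(0, 390, 30)]
        w = ch.determine_episode_end(rxs, [], IDX, class_map)
        assert w.end_day == 365 and not w.episode_ended

    def test_antipsychotic_supply_is_not_episode_activity(self, class_map):
        w = ch.determine_episode_end(
            [rx(0, "sertraline", 30), rx(60, "quetiapine", 300)], [], IDX, class_map
        )
        assert w.end_day == 30

    def test_idempotent_under_truncation(self, class_map):
        rxs = [rx(0, "sertraline", 30), rx(40, "sertraline", 30), rx(250, "sertraline", 30)]
        w1 = ch.determine_episode_end(rxs, [], IDX, class_map)
        cut = IDX + dt.timedelta(days=w1.end_day)
        w2 = ch.determine_episode_end([r for r in rxs if r.dispense_date < cut], [], IDX, class_map)
        assert w1.end_day == w2.end_day

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        days=st.lists(st.integers(0, 500), min_size=1, max_size=12),
        supplies=st.lists(st.integers(1, 60), min_size=12, max_size=12),
        gap_pair=st.tuples(st.integers(30, 200), st.integers(0, 150)),
    )
    def test_longer_gap_never_shortens_episode(self, class_map, days, supplies, gap_pair):
        rxs = [rx(d, "sertraline", s) for d, s in zip(sorted({0, *days}), supplies)]
        g1, extra = gap_pair
        e1 = ch.determine_episode_end(rxs, [], IDX, class_map, gap_days=g1).end_day
        e2 = ch.determine_episode_end(rxs, [], IDX, class_map, gap_days=g1 + extra).end_day
        assert e2 >= e1


class TestBuildCohort:
    def test_empty_input_gives_empty_cohort(self, class_map, config):
        cohort, att = ch.build_cohort([], [], [], class_map, config)
        assert cohort == [] and att["n"].sum() == 0

    def test_attrition_conservation(self, small_run):
        att = small_run["attrition"].set_index("stage")["n"]
        excluded = att[[i for i in att.index if i.startswith("excluded_")]].sum()
        assert att["candidates"] - excluded == att["eligible"]

    def test_all_eligible_cohort_has_zero_exclusions(self, small_run):
        att = small_run["attrition"].set_index("stage")["n"]
        assert (att[[i for i in att.index if i.startswith("excluded_")]] == 0).all()
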