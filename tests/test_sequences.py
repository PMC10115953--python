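import datetime as dt

import numpy as np
import pytest

from trajmine import sequences as sq
from trajmine.cohort import FollowUpWindow
from trajmine.data_model import PrescriptionRecord

IDX = dt.date(2015, 3, 1)


def rx(day, drug, supply=30, pid="p1"):
    return PrescriptionRecord(pid, IDX + dt.timedelta(days=day), drug, supply)


def window(end_day, pid="p1"):
    return FollowUpWindow(pid, IDX, end_day, end_day < 365)


def episodes(*specs, class_map=None):
    return [
        sq.DrugEpisode(drug, class_map.drug_class(drug), s, e, e - s)
        for drug, s, e in specs
    ]


class TestDrugEpisodes:
    def test_abutting_supplies_merge(self, class_map):
        eps = sq.build_drug_episodes([rx(0, "sertraline"), rx(30, "sertraline")], class_map, IDX)
        assert len(eps) == 1
        assert (eps[0].start_day, eps[0].end_day, eps[0].total_supply) == (0, 60, 60)

    def test_gap_beyond_refill_gap_splits(self, class_map):
        eps = sq.build_drug_episodes([rx(0, "sertraline"), rx(90, "sertraline")], class_map, IDX)
        assert [(e.start_day, e.end_day) for e in eps] == [(0, 30), (90, 120)]

    def test_gap_within_refill_gap_bridged(self, class_map):
        eps = sq.build_drug_episodes([rx(0, "sertraline"), rx(50, "sertraline")], class_map, IDX)
        assert [(e.start_day, e.end_day) for e in eps] == [(0, 80)]
        assert eps[0].total_supply == 60

    def test_different_drugs_stay_separate(self, class_map):
        eps = sq.build_drug_episodes([rx(0, "sertraline"), rx(10, "venlafaxine")], class_map, IDX)
        assert len(eps) == 2


class TestRegimenEvents:
    def test_switch_prior_drug_ends_within_window(self, class_map):
        eps = episodes(("sertraline", 0, 90), ("venlafaxine", 60, 150), class_map=class_map)
        ev, = sq.detect_regimen_events(eps)
        assert (ev.day, ev.kind, ev.resulting_step) == (60, "switch", 2)
        assert ev.leaving_drugs == {"sertraline"} and ev.entering_drugs == {"venlafaxine"}

    def test_addon_prior_drug_remains_active(self, class_map):
        eps = episodes(("sertraline", 0, 181), ("venlafaxine", 60, 150), class_map=class_map)
        ev, = sq.detect_regimen_events(eps)
        assert (ev.day, ev.kind) == (60, "addon")

    def test_short_supply_generates_no_event(self, class_map):
        eps = [
            sq.DrugEpisode("sertraline", "SSRI", 0, 90, 90),
            sq.DrugEpisode("venlafaxine", "SNRI", 60, 74, 14),
        ]
        assert sq.detect_regimen_events(eps) == []

    def test_simultaneous_starts_form_one_event(self, class_map):
        eps = episodes(
            ("sertraline", 0, 60), ("venlafaxine", 60, 150), ("mirtazapine", 60, 150),
            class_map=class_map,
        )
        ev, = sq.detect_regimen_events(eps)
        assert ev.entering_drugs == {"venlafaxine", "mirtazapine"} and ev.resulting_step == 2

    def test_steps_increment_across_events(self, class_map):
        eps = episodes(
            ("sertraline", 0, 60), ("venlafaxine", 60, 120), ("mirtazapine", 120, 180),
            class_map=class_map,
        )
        evs = sq.detect_regimen_events(eps)
        assert [e.resulting_step for e in evs] == [2, 3]

    def test_same_drug_restart_is_not_an_event(self, class_map):
        eps = sq.build_drug_episodes(
            [rx(0, "sertraline"), rx(100, "sertraline")], class_map, IDX
        )
        assert sq.detect_regimen_events(eps) == []


class TestChannelSequences:
    def test_single_drug_early_discontinuation(self, class_map):
        eps = episodes(("sertraline", 0, 35), class_map=class_map)
        seq = sq.build_channel_sequences(eps, [], window(35))
        assert seq.states("class")[:35] == ["SSRI"] * 35
        assert seq.states("class")[35:] == ["DISC"] * 330
        assert seq.states("step")[:35] == ["S1"] * 35
        assert seq.states("poly")[:35] == ["SINGLE"] * 35
        assert seq.end_day == 35

    def test_addon_marks_multi_exactly_on_overlap_days(self, class_map):
        eps = episodes(("sertraline", 0, 200), ("venlafaxine", 60, 150), class_map=class_map)
        evs = sq.detect_regimen_events(eps)
        seq = sq.build_channel_sequences(eps, evs, window(200))
        poly = np.array(seq.states("poly"))
        assert (poly[60:150] == "MULTI").all()
        assert (poly[:60] == "SINGLE").all() and (poly[150:200] == "SINGLE").all()

    def test_supply_gap_carries_last_state_forward(self, class_map):
        eps = episodes(("sertraline", 0, 30), ("sertraline", 50, 80), class_map=class_map)
        # gap days 30-49 inside the episode window: LOCF from day 29
        seq = sq.build_channel_sequences(eps, [], window(80))
        assert seq.states("class")[29:50] == ["SSRI"] * 21
        assert seq.states("poly")[30:50] == ["SINGLE"] * 20

    def test_class_on_multi_drug_day_is_latest_initiation(self, class_map):
        eps = episodes(("sertraline", 0, 200), ("venlafaxine", 60, 150), class_map=class_map)
        seq = sq.build_channel_sequences(eps, [], window(200))
        cls = seq.states("class")
        assert cls[59] == "SSRI" and cls[100] == "SNRI" and cls[160] == "SSRI"

    def test_same_day_start_tie_broken_by_class_priority(self, class_map):
        eps = episodes(("mirtazapine", 0, 100), ("sertraline", 0, 100), class_map=class_map)
        seq = sq.build_channel_sequences(eps, [], window(100))
        assert seq.states("class")[0] == "SSRI"

    def test_no_drug_on_day_zero_is_an_error(self, class_map):
        eps = episodes(("sertraline", 10, 40), class_map=class_map)
        with pytest.raises(ValueError, match="day 0"):
            sq.build_channel_sequences(eps, [], window(40))

    def test_step_channel_follows_events(self, class_map):
        eps = episodes(
            ("sertraline", 0, 60), ("venlafaxine", 60, 120), ("mirtazapine", 120, 240),
            class_map=class_map,
        )
        evs = sq.detect_regimen_events(eps)
        seq = sq.build_channel_sequences(eps, evs, window(240))
        step = seq.states("step")
        assert step[59] == "S1" and step[60] == "S2" and step[120] == "S3plus"


class TestSequenceInvariants:
    def test_all_channels_exactly_365_days(self, small_run):
        for s in small_run["sequences"]:
            assert len(s.class_seq) == len(s.step_seq) == len(s.poly_seq) == 365

    def test_disc_suffix_aligned_across_channels_and_matches_window(self, small_run):
        for cp, s in zip(small_run["cohort"], small_run["sequences"]):
            disc_class = s.class_seq == sq.CLASS_STATES.index("DISC")
            disc_step = s.step_seq == sq.STEP_STATES.index("DISC")
            disc_poly = s.poly_seq == sq.POLY_STATES.index("DISC")
            assert (disc_class == disc_step).all() and (disc_class == disc_poly).all()
            assert s.end_day == cp.window.end_day
            # suffix structure: once DISC, always DISC
            assert (np.diff(disc_class.astype(int)) >= 0).all()

    def test_step_channel_monotone_before_disc(self, small_run):
        for s in small_run["sequences"]:
            pre = s.step_seq[s.step_seq != sq.STEP_STATES.index("DISC")]
            assert (np.diff(pre) >= 0).all()

    def test_roundtrip_through_long_format(self, small_run):
        df = sq.sequences_to_frame(small_run["sequences"][:7])
        back = sq.frame_to_sequences(df)
        for a, b in zip(small_run["sequences"][:7], back):
            assert a.patient_id == b.patient_id
            assert (a.class_seq == b.class_seq).all()
            assert (a.step_seq == b.step_seq).all()
            assert (a.poly_seq == b.poly_seq).all()
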