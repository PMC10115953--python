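"""From prescriptions to three aligned 365-day state sequences per patient.

Channels (daily states, day 0 = index date, intervals half-open):

* **class** — which drug class the patient is on: SSRI, SNRI, TCA, NaSSA,
  OtherAD, AP, or DISC after the episode ends. On multi-drug days the channel
  shows the class of the most recently initiated active drug (ties broken by
  the fixed priority SSRI > SNRI > TCA > NaSSA > OtherAD > AP).
* **step** — cumulative regimen-change counter: S1 until the first switch or
  add-on, then S2, then S3plus, then DISC.
* **poly** — SINGLE vs MULTI (>= 2 distinct drugs in supply), then DISC.

A *switch* is the initiation of one or more different drugs with the prior
drug(s) discontinuing within +/- 30 days of the new start; an *add-on*
augments a continuing regimen. Either counts as a step only when the new
drug's episode totals >= 30 days of supply. Within-episode supply gaps are
imputed by carrying the last observed state forward (LOCF); days at or after
the episode end are DISC in all three channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import FollowUpWindow
from .data_model import ALL_CLASSES, DrugClassMap, PrescriptionRecord

CLASS_STATES = ALL_CLASSES + ("DISC",)
STEP_STATES = ("S1", "S2", "S3plus", "DISC")
POLY_STATES = ("SINGLE", "MULTI", "DISC")

CHANNELS = ("class", "step", "poly")
CHANNEL_STATES = {"class": CLASS_STATES, "step": STEP_STATES, "poly": POLY_STATES}

#: class priority for tie-breaking on multi-drug days (lower rank wins)
_CLASS_RANK = {c: i for i, c in enumerate(ALL_CLASSES)}


@dataclass(frozen=True)
class DrugEpisode:
    """A contiguous exposure to one drug, refill gaps <= refill_gap bridged."""

    drug_code: str
    drug_class: str
    start_day: int
    end_day: int  # half-open [start_day, end_day)
    total_supply: int

    def __post_init__(self):
        assert 0 <= self.start_day < self.end_day

    def active_at(self, day: int) -> bool:
        return self.start_day <= day < self.end_day


@dataclass(frozen=True)
class StepEvent:
    day: int
    kind: str  # "switch" | "addon"
    entering_drugs: frozenset
    leaving_drugs: frozenset
    resulting_step: int

    def __post_init__(self):
        assert self.kind in ("switch", "addon")
        if self.kind == "switch":
            assert self.leaving_drugs, "a switch must leave at least one drug"


@dataclass
class MultiChannelSequence:
    """Three aligned daily state vectors (integer-coded, length follow_up_days)."""

    patient_id: str
    class_seq: np.ndarray
    step_seq: np.ndarray
    poly_seq: np.ndarray

    def states(self, channel: str) -> list[str]:
        arr = getattr(self, f"{channel}_seq")
        return [CHANNEL_STATES[channel][i] for i in arr]

    @property
    def end_day(self) -> int:
        disc = int(np.argmax(self.class_seq == CLASS_STATES.index("DISC")))
        if self.class_seq[-1] != CLASS_STATES.index("DISC"):
            return len(self.class_seq)
        return disc


def build_drug_episodes(
    prescriptions: Sequence[PrescriptionRecord],
    class_map: DrugClassMap,
    index_date,
    refill_gap: int = 30,
) -> list[DrugEpisode]:
    """Merge one patient's post-index supplies into per-drug exposure episodes.

    Supply intervals [dispense, dispense + days_supply) of the same drug are
    merged when overlapping, abutting, or separated by <= ``refill_gap`` days.
    """
    by_drug: dict[str, list[tuple[int, int, int]]] = {}
    for p in prescriptions:
        s = (p.dispense_date - index_date).days
        if s < 0:
            continue
        by_drug.setdefault(p.drug_code, []).append((s, s + p.days_supply, p.days_supply))
    episodes: list[DrugEpisode] = []
    for drug, sup in by_drug.items():
        sup.sort()
        cls = class_map.drug_class(drug)
        cur_s, cur_e, cur_supply = sup[0]
        for s, e, q in sup[1:]:
            if s - cur_e <= refill_gap:
                cur_e = max(cur_e, e)
                cur_supply += q
            else:
                episodes.append(DrugEpisode(drug, cls, cur_s, cur_e, cur_supply))
                cur_s, cur_e, cur_supply = s, e, q
        episodes.append(DrugEpisode(drug, cls, cur_s, cur_e, cur_supply))
    episodes.sort(key=lambda ep: (ep.start_day, ep.drug_code))
    return episodes


def detect_regimen_events(
    drug_episodes: Sequence[DrugEpisode],
    min_supply: int = 30,
    switch_window: int = 30,
) -> list[StepEvent]:
    """Detect switches and add-ons; each increments the treatment step by one.

    A new-drug episode starting at day t (total supply >= ``min_supply``)
    triggers a switch when every previously active drug's episode ends within
    [t - switch_window, t + switch_window]; it is an add-on when at least one
    prior drug remains active more than ``switch_window`` days past t.
    Simultaneous starts form one event; a restart of a drug already seen is a
    refill, not an initiation, and triggers nothing.
    """
    episodes = sorted(drug_episodes, key=lambda ep: (ep.start_day, ep.drug_code))
    first_start: dict[str, int] = {}
    for ep in episodes:
        first_start.setdefault(ep.drug_code, ep.start_day)

    starts: dict[int, list[DrugEpisode]] = {}
    for ep in episodes:
        if ep.start_day == 0 or ep.total_supply < min_supply:
            continue
        if first_start[ep.drug_code] < ep.start_day:
            continue  # same-drug restart
        starts.setdefault(ep.start_day, []).append(ep)

    events: list[StepEvent] = []
    step = 1
    for t in sorted(starts):
        entering = frozenset(ep.drug_code for ep in starts[t])
        prior = [
            ep
            for ep in episodes
            if ep.start_day < t and ep.end_day > t - switch_window and ep.drug_code not in entering
        ]
        if prior:
            staying = [ep for ep in prior if ep.end_day > t + switch_window]
            leaving = frozenset(ep.drug_code for ep in prior if ep.end_day <= t + switch_window)
            kind = "addon" if staying else "switch"
        else:
            # regimen restarts with a different drug after a long pause: the
            # most recently active drugs are considered replaced
            prev = [ep for ep in episodes if ep.end_day <= t - switch_window]
            last_end = max((ep.end_day for ep in prev), default=None)
            leaving = frozenset(ep.drug_code for ep in prev if ep.end_day == last_end)
            kind = "switch" if leaving else "addon"
        step += 1
        events.append(
            StepEvent(day=t, kind=kind, entering_drugs=entering, leaving_drugs=leaving,
                      resulting_step=step)
        )
    return events


def build_channel_sequences(
    drug_episodes: Sequence[DrugEpisode],
    step_events: Sequence[StepEvent],
    window: FollowUpWindow,
    follow_up_days: int = 365,
    patient_id: str | None = None,
) -> MultiChannelSequence:
    """Emit the three aligned daily sequences for one patient."""
    end_day = min(window.end_day, follow_up_days)
    disc_class = CLASS_STATES.index("DISC")
    disc_step = STEP_STATES.index("DISC")
    disc_poly = POLY_STATES.index("DISC")

    class_seq = np.full(follow_up_days, disc_class, dtype=np.int8)
    step_seq = np.full(follow_up_days, disc_step, dtype=np.int8)
    poly_seq = np.full(follow_up_days, disc_poly, dtype=np.int8)

    # paint class states: episodes in start order; for same-day starts the
    # higher-priority class is painted last so it wins the tie
    paint = np.full(end_day, -1, dtype=np.int8)
    count = np.zeros(end_day, dtype=np.int16)
    for ep in sorted(drug_episodes, key=lambda e: (e.start_day, -_CLASS_RANK[e.drug_class])):
        s, e = max(ep.start_day, 0), min(ep.end_day, end_day)
        if s < e:
            paint[s:e] = CLASS_STATES.index(ep.drug_class)
            count[s:e] += 1
    if end_day > 0 and count[0] == 0:
        raise ValueError("no active drug on day 0: contradicts the index definition")

    # LOCF over uncovered days strictly before end_day
    for d in range(1, end_day):
        if count[d] == 0:
            paint[d] = paint[d - 1]
    class_seq[:end_day] = paint

    poly = np.where(count >= 2, POLY_STATES.index("MULTI"), POLY_STATES.index("SINGLE"))
    for d in range(1, end_day):
        if count[d] == 0:
            poly[d] = poly[d - 1]
    poly_seq[:end_day] = poly

    event_days = np.array(sorted(ev.day for ev in step_events), dtype=np.int64)
    days = np.arange(end_day)
    step_no = 1 + np.searchsorted(event_days, days, side="right")
    step_seq[:end_day] = np.minimum(step_no, 3) - 1  # codes: 0=S1, 1=S2, 2=S3plus

    return MultiChannelSequence(
        patient_id=patient_id or window.patient_id,
        class_seq=class_seq,
        step_seq=step_seq,
        poly_seq=poly_seq,
    )


def build_patient_sequence(
    prescriptions: Sequence[PrescriptionRecord],
    window: FollowUpWindow,
    class_map: DrugClassMap,
    index_date,
    refill_gap: int = 30,
    min_supply: int = 30,
    switch_window: int = 30,
    follow_up_days: int = 365,
) -> tuple[MultiChannelSequence, list[StepEvent]]:
    """Convenience wrapper: episodes -> events -> channels for one patient."""
    episodes = build_drug_episodes(prescriptions, class_map, index_date, refill_gap)
    events = detect_regimen_events(episodes, min_supply, switch_window)
    seq = build_channel_sequences(episodes, events, window, follow_up_days)
    return seq, events


def sequences_to_frame(sequences: Sequence[MultiChannelSequence]) -> pd.DataFrame:
    """Long-format export: patient_id, day, class_state, step_state, poly_state."""
    frames = []
    for s in sequences:
        n = len(s.class_seq)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "day": np.arange(n),
                    "class_state": [CLASS_STATES[i] for i in s.class_seq],
                    "step_state": [STEP_STATES[i] for i in s.step_seq],
                    "poly_state": [POLY_STATES[i] for i in s.poly_seq],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_sequences(df: pd.DataFrame) -> list[MultiChannelSequence]:
    """Inverse of :func:`sequences_to_frame`."""
    out = []
    class_code = {s: i for i, s in enumerate(CLASS_STATES)}
    step_code = {s: i for i, s in enumerate(STEP_STATES)}
    poly_code = {s: i for i, s in enumerate(POLY_STATES)}
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("day")
        out.append(
            MultiChannelSequence(
                patient_id=str(pid),
                class_seq=np.array([class_code[s] for s in g["class_state"]], dtype=np.int8),
                step_seq=np.array([step_code[s] for s in g["step_state"]], dtype=np.int8),
                poly_seq=np.array([poly_code[s] for s in g["poly_state"]], dtype=np.int8),
            )
        )
    return out
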