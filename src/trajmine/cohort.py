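"""Cohort construction: index prescription, eligibility cascade, follow-up window.

A patient enters the cohort at the *index date*: the first antidepressant (AD)
dispensing in the study year preceded by a clean washout (no AD use in the
prior ``washout_days``, default 365). Eligibility rules are applied in a fixed
order so that attrition counts are comparable across runs:

1. comorbid diagnosis — bipolar disorder (F30.x/F31.x), schizophrenia (F20.x)
   or organic CNS disease (F00.x–F09.x) in baseline or follow-up;
2. electroconvulsive therapy in baseline (input flag);
3. age at index outside [18, 65] completed years;
4. two or more distinct ADs dispensed on the index date (monotherapy start
   required);
5. no major-depressive-disorder diagnosis (F32.x/F33.x) in baseline.

Follow-up runs up to 365 days from index or until the first treatment episode
ends, whichever comes first. An episode is considered ended when 120 days pass
with neither an AD supply in hand nor a depression diagnosis.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .config import RunConfig
from .data_model import (
    DiagnosisRecord,
    DrugClassMap,
    PatientRecord,
    PrescriptionRecord,
)

EXCLUSION_ORDER = (
    "no_ad",
    "comorbid_dx",
    "ect_baseline",
    "age",
    "multi_ad_index",
    "no_mdd_dx",
)

_COMORBID_PREFIXES = ("F20", "F30", "F31")
_MDD_PREFIXES = ("F32", "F33")


@dataclass(frozen=True)
class IndexInfo:
    patient_id: str
    index_date: dt.date
    index_drug: str
    index_class: str


@dataclass(frozen=True)
class EligibilityResult:
    patient_id: str
    eligible: bool
    exclusion_reason: str  # "none" or one of EXCLUSION_ORDER
    applied_order: int

    def __post_init__(self):
        assert self.eligible == (self.exclusion_reason == "none")


@dataclass(frozen=True)
class FollowUpWindow:
    patient_id: str
    start: dt.date
    end_day: int  # days since index, exclusive; in [1, 365]
    episode_ended: bool


@dataclass(frozen=True)
class CohortPatient:
    """A fully-resolved eligible patient, ready for sequence construction."""

    patient_id: str
    index: IndexInfo
    window: FollowUpWindow
    sex: str
    age_at_index: int


def _is_comorbid(code: str) -> bool:
    code = code.upper()
    if code.startswith(_COMORBID_PREFIXES):
        return True
    # F00.x - F09.x: organic CNS disease
    return len(code) >= 3 and code[0] == "F" and code[1] == "0" and code[2].isdigit()


def _is_mdd(code: str) -> bool:
    return code.upper().startswith(_MDD_PREFIXES)


def age_in_completed_years(birth_date: dt.date, on: dt.date) -> int:
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def find_index_prescription(
    patient_prescriptions: Sequence[PrescriptionRecord],
    class_map: DrugClassMap,
    study_year: int,
    washout_days: int = 365,
) -> IndexInfo | None:
    """Earliest in-year AD dispensing with no AD use in the preceding washout.

    Antipsychotics are never index-eligible and do not count as prior AD use.
    Returns ``None`` when no dispensing qualifies (a valid outcome).
    """
    ad_rx = sorted(
        (p for p in patient_prescriptions if class_map.is_ad(p.drug_code)),
        key=lambda p: (p.dispense_date, p.drug_code),
    )
    for p in ad_rx:
        if p.dispense_date.year != study_year:
            continue
        lo = p.dispense_date - dt.timedelta(days=washout_days)
        if any(lo <= q.dispense_date < p.dispense_date for q in ad_rx):
            continue
        return IndexInfo(
            patient_id=p.patient_id,
            index_date=p.dispense_date,
            index_drug=p.drug_code,
            index_class=class_map.drug_class(p.drug_code),
        )
    return None


def apply_eligibility(
    patient: PatientRecord,
    index_info: IndexInfo | None,
    diagnoses: Sequence[DiagnosisRecord],
    prescriptions: Sequence[PrescriptionRecord],
    class_map: DrugClassMap,
    config: RunConfig | None = None,
) -> EligibilityResult:
    """Apply the exclusion cascade in fixed order; the first failing rule wins."""
    config = config or RunConfig()
    pid = patient.patient_id

    def excluded(reason: str) -> EligibilityResult:
        return EligibilityResult(
            patient_id=pid,
            eligible=False,
            exclusion_reason=reason,
            applied_order=EXCLUSION_ORDER.index(reason) + 1,
        )

    if index_info is None:
        return excluded("no_ad")
    idx = index_info.index_date
    baseline_lo = idx - dt.timedelta(days=config.washout_days)
    followup_hi = idx + dt.timedelta(days=config.follow_up_days)

    # (1) comorbid dx in baseline or follow-up
    if any(baseline_lo <= d.date <= followup_hi and _is_comorbid(d.icd10) for d in diagnoses):
        return excluded("comorbid_dx")
    # (2) baseline ECT
    if patient.ect_baseline:
        return excluded("ect_baseline")
    # (3) age at index in completed years
    if patient.birth_date is None:
        raise ValueError(f"patient {pid}: birth_date missing, age rule unevaluable")
    age = age_in_completed_years(patient.birth_date, idx)
    if not (18 <= age <= 65):
        return excluded("age")
    # (4) >= 2 distinct ADs on the index date
    index_ads = {
        p.drug_code
        for p in prescriptions
        if p.dispense_date == idx and class_map.is_ad(p.drug_code)
    }
    if len(index_ads) >= 2:
        return excluded("multi_ad_index")
    # (5) MDD diagnosis required in baseline
    if not any(baseline_lo <= d.date <= idx and _is_mdd(d.icd10) for d in diagnoses):
        return excluded("no_mdd_dx")
    return EligibilityResult(patient_id=pid, eligible=True, exclusion_reason="none", applied_order=0)


def determine_episode_end(
    prescriptions_after_index: Sequence[PrescriptionRecord],
    diagnoses_after_index: Sequence[DiagnosisRecord],
    index_date: dt.date,
    class_map: DrugClassMap,
    gap_days: int = 120,
    follow_up_days: int = 365,
) -> FollowUpWindow:
    """Locate the end of the first treatment episode and cap it at 365 days.

    Activity is an AD supply in hand (the interval [dispense, dispense +
    days_supply)) or a depression diagnosis day (F32.x/F33.x). The episode ends
    at the first activity-chain endpoint followed by >= ``gap_days`` with
    neither kind of activity; trailing silence (end of records) counts as an
    unbounded gap.
    """
    pid = None
    intervals: list[tuple[int, int]] = []
    for p in prescriptions_after_index:
        if not class_map.is_ad(p.drug_code):
            continue
        pid = pid or p.patient_id
        s = (p.dispense_date - index_date).days
        if s < 0:
            continue
        intervals.append((s, s + p.days_supply))
    for d in diagnoses_after_index:
        if not _is_mdd(d.icd10):
            continue
        pid = pid or d.patient_id
        day = (d.date - index_date).days
        if day >= 0:
            intervals.append((day, day + 1))
    if not intervals:
        raise ValueError("no post-index activity: episode end undefined without an index supply")
    intervals.sort()
    end = intervals[0][1]
    for s, e in intervals[1:]:
        if s - end >= gap_days:
            break
        end = max(end, e)
    end_day = min(end, follow_up_days)
    return FollowUpWindow(
        patient_id=pid or "",
        start=index_date,
        end_day=max(end_day, 1),
        episode_ended=end < follow_up_days,
    )


def build_cohort(
    prescriptions: Iterable[PrescriptionRecord],
    diagnoses: Iterable[DiagnosisRecord],
    patients: Iterable[PatientRecord],
    class_map: DrugClassMap,
    config: RunConfig | None = None,
) -> tuple[list[CohortPatient], pd.DataFrame]:
    """Run the full cascade over all patients; return cohort and attrition table.

    The attrition table lists, in application order, the count removed by each
    rule and the final cohort size; counts always sum to the candidate count.
    """
    config = config or RunConfig()
    rx_by_pid: dict[str, list[PrescriptionRecord]] = {}
    for p in prescriptions:
        rx_by_pid.setdefault(p.patient_id, []).append(p)
    dx_by_pid: dict[str, list[DiagnosisRecord]] = {}
    for d in diagnoses:
        dx_by_pid.setdefault(d.patient_id, []).append(d)

    patients = list(patients)
    counts = {reason: 0 for reason in EXCLUSION_ORDER}
    cohort: list[CohortPatient] = []
    for pt in patients:
        rx = rx_by_pid.get(pt.patient_id, [])
        dx = dx_by_pid.get(pt.patient_id, [])
        index_info = find_index_prescription(rx, class_map, config.study_year, config.washout_days)
        res = apply_eligibility(pt, index_info, dx, rx, class_map, config)
        if not res.eligible:
            counts[res.exclusion_reason] += 1
            continue
        assert index_info is not None
        window = determine_episode_end(
            [p for p in rx if p.dispense_date >= index_info.index_date],
            [d for d in dx if d.date >= index_info.index_date],
            index_info.index_date,
            class_map,
            gap_days=config.episode_gap_days,
            follow_up_days=config.follow_up_days,
        )
        cohort.append(
            CohortPatient(
                patient_id=pt.patient_id,
                index=index_info,
                window=FollowUpWindow(
                    patient_id=pt.patient_id,
                    start=window.start,
                    end_day=window.end_day,
                    episode_ended=window.episode_ended,
                ),
                sex=pt.sex,
                age_at_index=age_in_completed_years(pt.birth_date, index_info.index_date),
            )
        )

    rows = [("candidates", len(patients))]
    rows += [(f"excluded_{r}", counts[r]) for r in EXCLUSION_ORDER]
    rows.append(("eligible", len(cohort)))
    attrition = pd.DataFrame(rows, columns=["stage", "n"])
    assert len(patients) - sum(counts.values()) == len(cohort)
    return cohort, attrition
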