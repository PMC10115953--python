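"""Typed EHR tables: prescriptions, diagnoses, patients, and the drug-class map.

The raw inputs are three delimited-text tables (comma-separated, UTF-8,
ISO-8601 dates, mandatory header row):

* ``prescriptions(patient_id, dispense_date, drug_code, days_supply, setting)``
* ``diagnoses(patient_id, date, icd10)``
* ``patients(patient_id, birth_date, sex[, ect_baseline])``

plus a drug-class map ``(drug_code, class)`` assigning every prescribable
drug to one of six classes: the five antidepressant classes SSRI, SNRI, TCA,
NaSSA, OtherAD, and AP (antipsychotics, used as augmentation agents).
Antipsychotics are never eligible as an index drug.

Validation is total: every row either becomes a typed record or raises an
error carrying its line number; rows are never dropped silently.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

AD_CLASSES = ("SSRI", "SNRI", "TCA", "NaSSA", "OtherAD")
ALL_CLASSES = AD_CLASSES + ("AP",)

SETTINGS = ("outpatient", "inpatient")
SEXES = ("female", "male")

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowError(ValueError):
    """A data row violates a field invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DrugLookupError(KeyError):
    """A drug code is absent from the class map (no silent default)."""


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    dispense_date: dt.date
    drug_code: str
    days_supply: int
    setting: str = "outpatient"

    def __post_init__(self):
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: dt.date
    icd10: str

    def __post_init__(self):
        if not _ICD10_RE.match(self.icd10):
            raise ValueError(f"icd10 code {self.icd10!r} does not match letter+digits pattern")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    birth_date: dt.date
    sex: str
    ect_baseline: bool = False

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class DrugClassMap:
    """Mapping drug_code -> class label; AP is never eligible as index drug."""

    mapping: Mapping[str, str]
    eligible_as_index: Mapping[str, bool] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bad = {c for c in self.mapping.values() if c not in ALL_CLASSES}
        if bad:
            raise ValueError(f"unknown class labels {sorted(bad)}; allowed: {ALL_CLASSES}")
        elig = {c: c != "AP" for c in ALL_CLASSES}
        if self.eligible_as_index is not None:
            elig.update(self.eligible_as_index)
        if elig.get("AP", False):
            raise ValueError("AP can never be eligible_as_index")
        object.__setattr__(self, "eligible_as_index", elig)

    def __len__(self) -> int:
        return len(self.mapping)

    def drug_class(self, drug_code: str) -> str:
        try:
            return self.mapping[drug_code]
        except KeyError:
            raise DrugLookupError(f"drug code {drug_code!r} not in class map") from None

    def index_eligible(self, drug_code: str) -> bool:
        return self.eligible_as_index[self.drug_class(drug_code)]

    def is_ad(self, drug_code: str) -> bool:
        """True for the five antidepressant classes (AP excluded)."""
        return self.drug_class(drug_code) in AD_CLASSES


def map_drug_class(drug_code: str, class_map: DrugClassMap) -> str:
    """Resolve a drug code to its class label; unmapped codes are a hard error."""
    if len(class_map) == 0:
        raise ValueError("class map is empty")
    return class_map.drug_class(drug_code)


def _parse_date(value: str, line: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError:
        raise RowError(f"column {column!r}: unparseable ISO-8601 date {value!r}", line) from None


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_prescriptions(path) -> list[PrescriptionRecord]:
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "dispense_date", "drug_code", "days_supply"], path)
    has_setting = "setting" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            supply = int(d["days_supply"])
        except ValueError:
            raise RowError(f"days_supply {d['days_supply']!r} is not an integer", line) from None
        try:
            out.append(
                PrescriptionRecord(
                    patient_id=d["patient_id"],
                    dispense_date=_parse_date(d["dispense_date"], line, "dispense_date"),
                    drug_code=d["drug_code"],
                    days_supply=supply,
                    setting=d["setting"] if has_setting else "outpatient",
                )
            )
        except ValueError as e:
            if isinstance(e, RowError):
                raise
            raise RowError(str(e), line) from None
    return out


def read_diagnoses(path) -> list[DiagnosisRecord]:
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "date", "icd10"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        d = dict(zip(df.columns, row))
        try:
            out.append(
                DiagnosisRecord(
                    patient_id=d["patient_id"],
                    date=_parse_date(d["date"], line, "date"),
                    icd10=d["icd10"].strip(),
                )
            )
        except ValueError as e:
            if isinstance(e, RowError):
                raise
            raise RowError(str(e), line) from None
    return out


def read_patients(path) -> list[PatientRecord]:
    df = _read_csv(path)
    _require_columns(df, ["patient_id", "birth_date", "sex"], path)
    has_ect = "ect_baseline" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        d = dict(zip(df.columns, row))
        ect = d["ect_baseline"].strip().lower() in ("1", "true", "yes") if has_ect else False
        try:
            out.append(
                PatientRecord(
                    patient_id=d["patient_id"],
                    birth_date=_parse_date(d["birth_date"], line, "birth_date"),
                    sex=d["sex"].strip(),
                    ect_baseline=ect,
                )
            )
        except ValueError as e:
            if isinstance(e, RowError):
                raise
            raise RowError(str(e), line) from None
    return out


def read_class_map(path) -> DrugClassMap:
    df = _read_csv(path)
    _require_columns(df, ["drug_code", "class"], path)
    return DrugClassMap(mapping=dict(zip(df["drug_code"], df["class"])))


def read_ehr_tables(
    prescriptions_path, diagnoses_path, patients_path
) -> tuple[list[PrescriptionRecord], list[DiagnosisRecord], list[PatientRecord]]:
    """Read and validate the three raw EHR tables, preserving row order."""
    return (
        read_prescriptions(prescriptions_path),
        read_diagnoses(diagnoses_path),
        read_patients(patients_path),
    )


def write_prescriptions(records: list[PrescriptionRecord], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "dispense_date": [r.dispense_date.isoformat() for r in records],
            "drug_code": [r.drug_code for r in records],
            "days_supply": [r.days_supply for r in records],
            "setting": [r.setting for r in records],
        }
    ).to_csv(path, index=False)


def write_diagnoses(records: list[DiagnosisRecord], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "icd10": [r.icd10 for r in records],
        }
    ).to_csv(path, index=False)


def write_patients(records: list[PatientRecord], path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "birth_date": [r.birth_date.isoformat() for r in records],
            "sex": [r.sex for r in records],
            "ect_baseline": [int(r.ect_baseline) for r in records],
        }
    ).to_csv(path, index=False)


def write_class_map(class_map: DrugClassMap, path) -> None:
    pd.DataFrame(
        {"drug_code": list(class_map.mapping), "class": list(class_map.mapping.values())}
    ).to_csv(path, index=False)


def default_class_map() -> DrugClassMap:
    """A small, editable default map of common antidepressants and augmentation APs.

    Ships as config, not as a claim about any particular formulary; users with
    their own drug dictionary should supply a CSV via :func:`read_class_map`.
    """
    return DrugClassMap(
        mapping={
            "sertraline": "SSRI",
            "escitalopram": "SSRI",
            "fluoxetine": "SSRI",
            "paroxetine": "SSRI",
            "venlafaxine": "SNRI",
            "duloxetine": "SNRI",
            "amitriptyline": "TCA",
            "clomipramine": "TCA",
            "mirtazapine": "NaSSA",
            "bupropion": "OtherAD",
            "trazodone": "OtherAD",
            "quetiapine": "AP",
            "olanzapine": "AP",
        }
    )
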