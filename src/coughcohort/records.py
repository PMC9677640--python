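"""In-memory claims containers and study-period bookkeeping.

Claims live in three pandas DataFrames bundled in :class:`ClaimsBundle`.
Months are held as integer month indices (``YearMonth.value``) so window
arithmetic is plain integer arithmetic; prescription dates are
``datetime64[ns]``.  The TSV readers/writers in :mod:`coughcohort.io` convert
to and from ISO strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .months import YearMonth, ym

GENDERS = ("male", "female")
FACILITY_SIZES = ("beds_1_19", "beds_20_199", "beds_200_plus", "unknown")

#: In-memory column schemas.
BENEFICIARY_COLS = ("id", "birth_m", "gender")
DIAGNOSIS_COLS = ("beneficiary_id", "month", "icd10", "standard_name", "facility_size")
PRESCRIPTION_COLS = ("beneficiary_id", "date", "atc")


def empty_beneficiaries() -> pd.DataFrame:
    return pd.DataFrame({"id": pd.Series(dtype=str),
                         "birth_m": pd.Series(dtype=np.int64),
                         "gender": pd.Series(dtype=str)})


def empty_diagnoses() -> pd.DataFrame:
    return pd.DataFrame({"beneficiary_id": pd.Series(dtype=str),
                         "month": pd.Series(dtype=np.int64),
                         "icd10": pd.Series(dtype=str),
                         "standard_name": pd.Series(dtype=str),
                         "facility_size": pd.Series(dtype=str)})


def empty_prescriptions() -> pd.DataFrame:
    return pd.DataFrame({"beneficiary_id": pd.Series(dtype=str),
                         "date": pd.Series(dtype="datetime64[ns]"),
                         "atc": pd.Series(dtype=str)})


@dataclass
class ClaimsBundle:
    """The three claims tables of one dataset."""

    beneficiaries: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame

    def validate(self) -> "ClaimsBundle":
        for frame, cols, name in (
            (self.beneficiaries, BENEFICIARY_COLS, "beneficiaries"),
            (self.diagnoses, DIAGNOSIS_COLS, "diagnoses"),
            (self.prescriptions, PRESCRIPTION_COLS, "prescriptions"),
        ):
            missing = set(cols) - set(frame.columns)
            if missing:
                raise ValueError(f"{name} table missing columns: {sorted(missing)}")
        if self.beneficiaries["id"].duplicated().any():
            dup = self.beneficiaries.loc[self.beneficiaries["id"].duplicated(), "id"]
            raise ValueError(f"duplicate beneficiary ids: {sorted(set(dup))[:5]}")
        known = set(self.beneficiaries["id"])
        for frame, name in ((self.diagnoses, "diagnoses"), (self.prescriptions, "prescriptions")):
            stray = set(frame["beneficiary_id"]) - known
            if stray:
                raise ValueError(f"{name} reference unknown beneficiaries: {sorted(stray)[:5]}")
        return self

    @classmethod
    def empty(cls) -> "ClaimsBundle":
        return cls(empty_beneficiaries(), empty_diagnoses(), empty_prescriptions())


def rx_months(prescriptions: pd.DataFrame) -> pd.Series:
    """Integer month index of each prescription date."""
    d = prescriptions["date"]
    return 12 * d.dt.year + (d.dt.month - 1)


@dataclass(frozen=True)
class StudyPeriods:
    """The fixed calendar windows of the study design.

    The selection period is when index months may fall; the study period
    extends it by the 6-month pre-index history requirement at the front and
    the 12-month post-index follow-up at the back.
    """

    study_start: YearMonth = ym(2017, 1)
    selection_start: YearMonth = ym(2017, 7)
    selection_end: YearMonth = ym(2019, 8)
    observation_end: YearMonth = ym(2020, 8)

    def __post_init__(self):
        if self.study_start != self.selection_start - 6:
            raise ValueError("study_start must be selection_start - 6 months")
        if self.observation_end != self.selection_end + 12:
            raise ValueError("observation_end must be selection_end + 12 months")

    @property
    def n_months(self) -> int:
        return self.observation_end - self.study_start + 1

    def contains(self, m: YearMonth) -> bool:
        return self.study_start <= m <= self.observation_end

    def in_selection(self, m: YearMonth) -> bool:
        return self.selection_start <= m <= self.selection_end

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyPeriods":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            study_start=YearMonth.parse(str(raw["study_start"])),
            selection_start=YearMonth.parse(str(raw["selection_start"])),
            selection_end=YearMonth.parse(str(raw["selection_end"])),
            observation_end=YearMonth.parse(str(raw["observation_end"])),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "study_start": str(self.study_start),
            "selection_start": str(self.selection_start),
            "selection_end": str(self.selection_end),
            "observation_end": str(self.observation_end),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
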