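"""Readers and writers for the tab-delimited claims tables.

File layout (UTF-8, header row, tab-delimited):

* ``beneficiaries.tsv`` — id, birth_ym (YYYY-MM), gender
* ``diagnoses.tsv`` — beneficiary_id, ym (YYYY-MM), icd10, standard_name,
  facility_size
* ``prescriptions.tsv`` — beneficiary_id, date (YYYY-MM-DD), atc

Unparseable rows are reported with their 1-based line number (header = line 1).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd

from .months import YearMonth
from .records import (
    ClaimsBundle,
    FACILITY_SIZES,
    GENDERS,
    empty_beneficiaries,
    empty_diagnoses,
    empty_prescriptions,
)

BENEFICIARIES_TSV = "beneficiaries.tsv"
DIAGNOSES_TSV = "diagnoses.tsv"
PRESCRIPTIONS_TSV = "prescriptions.tsv"

_FILE_COLS = {
    BENEFICIARIES_TSV: ["id", "birth_ym", "gender"],
    DIAGNOSES_TSV: ["beneficiary_id", "ym", "icd10", "standard_name", "facility_size"],
    PRESCRIPTIONS_TSV: ["beneficiary_id", "date", "atc"],
}


class SchemaError(ValueError):
    """A file is missing a required column."""


class RowError(ValueError):
    """A row failed to parse; carries the file and 1-based line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _read_table(path: Path, name: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_FILE_COLS[name]) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return frame


def _parse_ym(text: str, path: Path, line: int, what: str) -> int:
    try:
        return YearMonth.parse(text).value
    except ValueError as exc:
        raise RowError(path, line, f"bad {what}: {exc}") from None


def read_claims(claims_dir: str | Path) -> ClaimsBundle:
    """Read and validate the three claims tables from ``claims_dir``."""
    claims_dir = Path(claims_dir)

    bpath = claims_dir / BENEFICIARIES_TSV
    braw = _read_table(bpath, BENEFICIARIES_TSV)
    if len(braw):
        birth_m = [
            _parse_ym(v, bpath, i + 2, "birth_ym")
            for i, v in enumerate(braw["birth_ym"])
        ]
        for i, g in enumerate(braw["gender"]):
            if g not in GENDERS:
                raise RowError(bpath, i + 2, f"bad gender: {g!r}")
        beneficiaries = pd.DataFrame(
            {"id": braw["id"], "birth_m": birth_m, "gender": braw["gender"]}
        )
    else:
        beneficiaries = empty_beneficiaries()

    dpath = claims_dir / DIAGNOSES_TSV
    draw = _read_table(dpath, DIAGNOSES_TSV)
    if len(draw):
        month = [
            _parse_ym(v, dpath, i + 2, "ym") for i, v in enumerate(draw["ym"])
        ]
        for i, (icd, fs) in enumerate(zip(draw["icd10"], draw["facility_size"])):
            if not icd:
                raise RowError(dpath, i + 2, "empty icd10 code")
            if fs not in FACILITY_SIZES:
                raise RowError(dpath, i + 2, f"bad facility_size: {fs!r}")
        diagnoses = pd.DataFrame(
            {
                "beneficiary_id": draw["beneficiary_id"],
                "month": month,
                "icd10": draw["icd10"],
                "standard_name": draw["standard_name"],
                "facility_size": draw["facility_size"],
            }
        )
    else:
        diagnoses = empty_diagnoses()

    ppath = claims_dir / PRESCRIPTIONS_TSV
    praw = _read_table(ppath, PRESCRIPTIONS_TSV)
    if len(praw):
        dates = []
        for i, v in enumerate(praw["date"]):
            try:
                dates.append(_dt.date.fromisoformat(v))
            except ValueError as exc:
                raise RowError(ppath, i + 2, f"bad date: {exc}") from None
        prescriptions = pd.DataFrame(
            {
                "beneficiary_id": praw["beneficiary_id"],
                "date": pd.to_datetime(dates),
                "atc": praw["atc"],
            }
        )
    else:
        prescriptions = empty_prescriptions()

    return ClaimsBundle(beneficiaries, diagnoses, prescriptions).validate()


def write_claims(bundle: ClaimsBundle, claims_dir: str | Path) -> None:
    """Write a bundle back to the three-TSV layout (inverse of read_claims)."""
    claims_dir = Path(claims_dir)
    claims_dir.mkdir(parents=True, exist_ok=True)

    b = bundle.beneficiaries
    pd.DataFrame(
        {
            "id": b["id"],
            "birth_ym": [str(YearMonth(int(v))) for v in b["birth_m"]],
            "gender": b["gender"],
        }
    ).to_csv(claims_dir / BENEFICIARIES_TSV, sep="\t", index=False)

    d = bundle.diagnoses
    pd.DataFrame(
        {
            "beneficiary_id": d["beneficiary_id"],
            "ym": [str(YearMonth(int(v))) for v in d["month"]],
            "icd10": d["icd10"],
            "standard_name": d["standard_name"],
            "facility_size": d["facility_size"],
        }
    ).to_csv(claims_dir / DIAGNOSES_TSV, sep="\t", index=False)

    p = bundle.prescriptions
    pd.DataFrame(
        {
            "beneficiary_id": p["beneficiary_id"],
            "date": p["date"].dt.strftime("%Y-%m-%d") if len(p) else p["date"],
            "atc": p["atc"],
        }
    ).to_csv(claims_dir / PRESCRIPTIONS_TSV, sep="\t", index=False)
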