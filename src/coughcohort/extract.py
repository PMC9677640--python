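"""Window extraction: cough codes, cough-related diseases, medication classes.

All counting is participant-level: a member counts once per category, disease
or medication class per window, regardless of how many claims fall inside.
Month windows are anchored to each member's index month and closed on both
ends; drug-utilisation windows at post-index months k use prescription dates
within ±14 days of the 15th of calendar month index+k, while the index-month
window is the whole index calendar month (the index day itself is unknown at
monthly diagnosis resolution).

Denominators follow the study conventions: index and pre-index windows use
the enrolled population, month-10-to-12 windows use the members still
"evaluable" there (at least one cough or cough-related-disease diagnosis
claim in months index+10 .. index+12), and medication windows use the members
with at least one prescription of any class of interest inside the window.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import pandas as pd

from .codebooks import (
    CLASSES_OF_INTEREST,
    COUGH_RELATED_DISEASES,
    Codebooks,
    CoughCategory,
    CoughCodebook,
    DiseaseCodebook,
    DiseaseLabel,
    MedicationClass,
    MedicationCodebook,
)
from .cohort import CohortAssignment
from .months import YearMonth

DIAGNOSIS_WINDOWS = ("index", "M10_12")
DISEASE_WINDOWS = ("index", "pre_index", "M10_12")
TIME_POINTS = ("index", 1, 2, 3, 6, 9, 12)


def _window_bounds(label: str, index_m: int) -> tuple[int, int]:
    if label == "index":
        return index_m, index_m
    if label == "pre_index":
        return index_m - 6, index_m
    if label == "M10_12":
        return index_m + 10, index_m + 12
    raise ValueError(f"unknown window label: {label!r}")


@dataclass
class DiagnosisWindowSummary:
    label: str
    counts: dict  # CoughCategory -> participant count
    denominator: int


@dataclass
class DiseaseWindowSummary:
    label: str
    counts: dict  # DiseaseLabel -> participant count
    denominator: int


@dataclass
class ClassCount:
    total: int = 0
    with_antitussive: int = 0
    without_antitussive: int = 0


@dataclass
class MedicationWindowSummary:
    time_point: object  # "index" or int month offset
    n_any: int  # members with >=1 prescription of interest in the window
    per_class: dict  # MedicationClass -> ClassCount
    antitussive_alone: int


# --- per-member claim maps --------------------------------------------------

def cough_months_by_member(diagnoses: pd.DataFrame, codebook: CoughCodebook, members) -> dict:
    """{member -> {month -> set of cough categories}} (all six categories)."""
    members = set(members)
    out: dict[str, dict] = {}
    for b, m, icd, name in zip(
        diagnoses["beneficiary_id"], diagnoses["month"],
        diagnoses["icd10"], diagnoses["standard_name"],
    ):
        if b not in members:
            continue
        cat = codebook.category(icd, name)
        if cat is not None:
            out.setdefault(b, {}).setdefault(int(m), set()).add(cat)
    return out


def disease_months_by_member(diagnoses: pd.DataFrame, codebook: DiseaseCodebook, members) -> dict:
    """{member -> {month -> set of cough-related disease labels}}."""
    members = set(members)
    label_of = {c: codebook.label(c) for c in pd.unique(diagnoses["icd10"])} if len(diagnoses) else {}
    out: dict[str, dict] = {}
    for b, m, icd in zip(
        diagnoses["beneficiary_id"], diagnoses["month"], diagnoses["icd10"]
    ):
        if b not in members:
            continue
        lbl = label_of.get(icd)
        if lbl is not None and not lbl.value.startswith("EXCL_"):
            out.setdefault(b, {}).setdefault(int(m), set()).add(lbl)
    return out


def _cats_in(by_month: dict, lo: int, hi: int) -> set:
    cats: set = set()
    for m, cs in by_month.items():
        if lo <= m <= hi:
            cats.update(cs)
    return cats


# --- diagnosis / disease windows -------------------------------------------

def member_cough_sets(members: dict, label: str, diagnoses: pd.DataFrame,
                      codebook: CoughCodebook) -> dict:
    """{member -> set of cough categories present in the member's window}."""
    by_member = cough_months_by_member(diagnoses, codebook, members)
    out = {}
    for b, a in members.items():
        lo, hi = _window_bounds(label, a.index_month.value)
        out[b] = _cats_in(by_member.get(b, {}), lo, hi)
    return out


def cough_categories_in(
    members: dict,
    label: str,
    diagnoses: pd.DataFrame,
    codebook: CoughCodebook,
    denominator: int | None = None,
) -> DiagnosisWindowSummary:
    """Participant counts per cough category inside each member's window.

    ``members`` maps beneficiary id to :class:`CohortAssignment`.  The
    denominator defaults to the number of members (index-window convention);
    month-10-to-12 summaries pass the evaluable-member count instead.
    """
    sets = member_cough_sets(members, label, diagnoses, codebook)
    counts = {cat: 0 for cat in CoughCategory}
    for cats in sets.values():
        for cat in cats:
            counts[cat] += 1
    return DiagnosisWindowSummary(
        label=label,
        counts=counts,
        denominator=len(members) if denominator is None else denominator,
    )


def diseases_in(
    members: dict,
    label: str,
    diagnoses: pd.DataFrame,
    codebook: DiseaseCodebook,
    denominator: int | None = None,
) -> DiseaseWindowSummary:
    """Participant counts per cough-related disease inside each window."""
    by_member = disease_months_by_member(diagnoses, codebook, members)
    counts = {d: 0 for d in COUGH_RELATED_DISEASES}
    for b, a in members.items():
        lo, hi = _window_bounds(label, a.index_month.value)
        for d in _cats_in(by_member.get(b, {}), lo, hi):
            counts[d] += 1
    return DiseaseWindowSummary(
        label=label,
        counts=counts,
        denominator=len(members) if denominator is None else denominator,
    )


def evaluable_at_m10_12(
    members: dict,
    diagnoses: pd.DataFrame,
    cough_codebook: CoughCodebook,
    disease_codebook: DiseaseCodebook,
) -> set:
    """Members with a cough or cough-related-disease diagnosis claim in
    months index+10 .. index+12 (prescriptions do not count)."""
    cough = cough_months_by_member(diagnoses, cough_codebook, members)
    disease = disease_months_by_member(diagnoses, disease_codebook, members)
    out = set()
    for b, a in members.items():
        lo, hi = _window_bounds("M10_12", a.index_month.value)
        if _cats_in(cough.get(b, {}), lo, hi) or _cats_in(disease.get(b, {}), lo, hi):
            out.add(b)
    return out


# --- medication windows -----------------------------------------------------

def _window_days(index_month: int, time_point) -> tuple[_dt.date, _dt.date]:
    """Closed day interval of a drug-utilisation window."""
    if time_point == "index" or time_point == 0:
        m = YearMonth(index_month)
        nxt = m + 1
        return m.first_day(), nxt.first_day() - _dt.timedelta(days=1)
    anchor = YearMonth(index_month + int(time_point)).day(15)
    return anchor - _dt.timedelta(days=14), anchor + _dt.timedelta(days=14)


def medication_window(
    index_month: YearMonth,
    time_point,
    prescriptions,
    codebook: MedicationCodebook,
) -> tuple[set, bool]:
    """Medication classes of one member in one window.

    ``prescriptions`` is an iterable of ``(date, atc)`` for the member.
    Returns the set of classes of interest present and whether a central
    antitussive falls in the same window (the per-class co-prescription
    flag — it is a property of the window, shared by every class in it).
    """
    lo, hi = _window_days(index_month.value, time_point)
    classes: set = set()
    for date, atc in prescriptions:
        if lo <= date <= hi:
            cls = codebook.label(atc)
            if cls is not None and cls is not MedicationClass.ACE_INHIBITOR:
                classes.add(cls)
    return classes, MedicationClass.CENTRAL_ANTITUSSIVE in classes


def rx_by_member(prescriptions: pd.DataFrame, members) -> dict:
    """{member -> list of (date, atc)} with dates as ``datetime.date``."""
    members = set(members)
    out: dict[str, list] = {}
    if not len(prescriptions):
        return out
    for b, ts, atc in zip(
        prescriptions["beneficiary_id"], prescriptions["date"], prescriptions["atc"]
    ):
        if b in members:
            out.setdefault(b, []).append((ts.date(), atc))
    return out


def medication_summary(
    members: dict,
    time_point,
    prescriptions: pd.DataFrame,
    codebook: MedicationCodebook,
    member_rx: dict | None = None,
) -> MedicationWindowSummary:
    """Per-class drug-utilisation counts for one time point.

    The denominator ``n_any`` is the number of members with at least one
    prescription of any class of interest inside the window.  Members whose
    window holds only a central antitussive are ``antitussive_alone``.
    A member counts under ``bronchodilator_other`` only when no ICS/LABA
    combination falls in the same window.
    """
    if member_rx is None:
        member_rx = rx_by_member(prescriptions, members)
    per_class = {c: ClassCount() for c in CLASSES_OF_INTEREST}
    n_any = 0
    alone = 0
    for b, a in members.items():
        classes, has_at = medication_window(
            a.index_month, time_point, member_rx.get(b, ()), codebook
        )
        if not classes:
            continue
        n_any += 1
        if classes == {MedicationClass.CENTRAL_ANTITUSSIVE}:
            alone += 1
        for cls in classes:
            if (
                cls is MedicationClass.BRONCHODILATOR_OTHER
                and MedicationClass.ICS_LABA in classes
            ):
                continue
            cc = per_class[cls]
            cc.total += 1
            if has_at:
                cc.with_antitussive += 1
            else:
                cc.without_antitussive += 1
    return MedicationWindowSummary(
        time_point=time_point, n_any=n_any, per_class=per_class, antitussive_alone=alone
    )
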