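"""Independent brute-force oracle for the cohort phenotype.

Deliberately naive: enumerate every (window start, index) pair over the whole
study period with set arithmetic, then re-apply the eligibility screens with
straight-line logic.  Kept free of any code path shared with the engine so it
can serve as an equivalence oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from coughcohort.codebooks import Codebooks, CoughCategory, MedicationClass
from coughcohort.months import YearMonth
from coughcohort.records import ClaimsBundle, StudyPeriods


def oracle_assign(bundle: ClaimsBundle, books: Codebooks, periods: StudyPeriods) -> dict:
    """{beneficiary_id: (population, index month value, subgroup frozenset)}"""
    out = {}
    dx = bundle.diagnoses
    rx = bundle.prescriptions
    for row in bundle.beneficiaries.itertuples(index=False):
        b = row.id
        bdx = dx[dx["beneficiary_id"] == b]
        brx = rx[rx["beneficiary_id"] == b]
        cats = {}  # month -> set of categories
        for m, icd, name in zip(bdx["month"], bdx["icd10"], bdx["standard_name"]):
            c = books.cough.category(icd, name)
            if c is not None:
                cats.setdefault(int(m), set()).add(c)

        chronic = {
            m for m, cs in cats.items()
            if CoughCategory.CHRONIC in cs
            and periods.selection_start.value <= m <= periods.selection_end.value
        }
        p2m = {m for m, cs in cats.items() if cs - {CoughCategory.CHRONIC}}

        population = index = window_start = None
        if chronic:
            population, index = "P1", min(chronic)
        else:
            # every (start, index) pair, earliest start then earliest index
            pairs = []
            for s in range(periods.study_start.value, periods.selection_end.value + 1):
                ev = {m for m in p2m if s <= m <= s + 2}
                post = {m for m in p2m if s + 3 <= m <= s + 5}
                if len(ev) >= 2 and post:
                    idx = min(post)
                    if periods.selection_start.value <= idx <= periods.selection_end.value:
                        pairs.append((s, idx))
            if pairs:
                window_start, index = min(pairs)
                population = "P2"
        if population is None:
            continue

        # eligibility screens
        months = {int(m) for m in bdx["month"]}
        months |= {ts.year * 12 + ts.month - 1 for ts in brx["date"]}
        if (index - int(row.birth_m)) // 12 < 20:
            continue
        if any(
            books.medication.label(a) is MedicationClass.ACE_INHIBITOR for a in brx["atc"]
        ):
            continue
        excl = False
        for icd in bdx["icd10"]:
            lbl = books.disease.label(icd)
            if lbl is not None and lbl.value.startswith("EXCL_"):
                excl = True
        if excl:
            continue
        if min(months) > index - 6:
            continue
        if not any(index + 1 <= m <= index + 12 for m in months):
            continue

        if population == "P2":
            sub = set()
            for m, cs in cats.items():
                if window_start <= m <= index:
                    sub |= cs - {CoughCategory.CHRONIC}
            subgroups = frozenset(sub)
        else:
            subgroups = frozenset()
        out[b] = (population, index, subgroups)
    return out


_COUGH_PAIRS = (
    ("R05", "chronic cough"),
    ("R05", "dry cough"),
    ("R05", "atopic cough"),
    ("J45.9", "cough-variant asthma"),
    ("R05", "post-infectious cough"),
    ("A37.9", "whooping cough"),
    ("R05", "cough"),
)


def random_bundle(rng: np.random.Generator, n: int, periods: StudyPeriods) -> ClaimsBundle:
    """A small adversarial bundle: dense cough claims, occasional exclusions."""
    lo, hi = periods.study_start.value, periods.observation_end.value
    ids = [f"R{i:04d}" for i in range(n)]
    birth = rng.integers(lo - 74 * 12, lo - 15 * 12, size=n)  # some minors
    genders = rng.choice(["male", "female"], size=n)

    dx_rows = []
    rx_rows = []
    for i, b in enumerate(ids):
        for _ in range(int(rng.integers(0, 12))):
            m = int(rng.integers(lo, hi + 1))
            icd, name = _COUGH_PAIRS[int(rng.integers(0, len(_COUGH_PAIRS)))]
            dx_rows.append((b, m, icd, name, "beds_1_19"))
        for _ in range(int(rng.integers(0, 4))):
            dx_rows.append((b, int(rng.integers(lo, hi + 1)), "Z00.0", "checkup", "beds_1_19"))
        if rng.random() < 0.08:
            dx_rows.append((b, int(rng.integers(lo, hi + 1)), "C50.9", "cancer", "unknown"))
        if rng.random() < 0.08:
            ym_v = int(rng.integers(lo, hi + 1))
            rx_rows.append((b, f"{ym_v // 12:04d}-{ym_v % 12 + 1:02d}-10", "C9A0"))
        if rng.random() < 0.5:
            ym_v = int(rng.integers(lo, hi + 1))
            rx_rows.append((b, f"{ym_v // 12:04d}-{ym_v % 12 + 1:02d}-15", "R05CB01"))

    beneficiaries = pd.DataFrame({"id": ids, "birth_m": birth, "gender": genders})
    diagnoses = pd.DataFrame(
        dx_rows, columns=["beneficiary_id", "month", "icd10", "standard_name", "facility_size"]
    )
    if rx_rows:
        prescriptions = pd.DataFrame(rx_rows, columns=["beneficiary_id", "date", "atc"])
        prescriptions["date"] = pd.to_datetime(prescriptions["date"])
    else:
        from coughcohort.records import empty_prescriptions

        prescriptions = empty_prescriptions()
    return ClaimsBundle(beneficiaries, diagnoses, prescriptions)
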