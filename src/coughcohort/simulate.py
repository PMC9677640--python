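"""Synthetic administrative-claims generator.

Emulates the structure the cohort algorithm assumes: month-stamped diagnosis
claims carrying (ICD-10, standard disease name) pairs, day-stamped ATC-coded
prescription claims, enrolment attrition, and a realistic age/sex mix.  The
generator can *plant* beneficiaries whose claim patterns satisfy the
Population 1 or Population 2 definition exactly, with the intended label,
index month and subgroup set recorded as ground truth for recovery testing.

What is emulated: monthly diagnosis resolution; R05 subtype disambiguation
through standard names; per-beneficiary cough-related disease prevalences
with conditional medication prescribing on uniformly random days of consult
months; ACE-inhibitor, organic-respiratory and cancer claims as exclusion
triggers; geometric enrolment dropout calibrated to an annual attrition rate.
What is not: physician coding behaviour, seasonal epidemics, entry churn
(all beneficiaries are present from the study start), or dose/duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .codebooks import CoughCategory, DEFAULT_COUGH_ROWS
from .months import YearMonth, ym
from .records import ClaimsBundle, StudyPeriods

# Representative diagnosis codes for the bundled stand-in disease codebook.
_DISEASE_CODES = {
    "ARNI": ("J30.4", "allergic rhinitis"),
    "asthma": ("J45.0", "asthma"),
    "GERD": ("K21.0", "reflux esophagitis"),
    "paranasal_sinusitis": ("J32.9", "chronic sinusitis"),
    "CAID": ("J44.8", "chronic airway inflammatory disease"),
    "chronic_rhinitis": ("J31.0", "chronic rhinitis"),
    "postnasal_drip": ("R09.8", "postnasal drip"),
    "vocal_cord_dysfunction": ("J38.3", "vocal cord dysfunction"),
    "emphysema": ("J43.9", "emphysema"),
    "nasal_polyps": ("J33.9", "nasal polyps"),
}
_EXCL_CODES = {
    "organic_respiratory": ("J84.9", "interstitial lung disease"),
    "cancer": ("C34.9", "lung cancer"),
}
_NEUTRAL_CODE = ("Z00.0", "general examination")  # maps to no category

# ATC leaves used for generated prescriptions (stand-in codebook leaves).
_ATC = {
    "central_antitussive": "R05DA01",
    "expectorant": "R05CB01",
    "antiallergic": "R06AE07",
    "antimicrobial_restricted": "J01FA10",
    "ICS_LABA": "R03AK06",
    "herbal": "V9000",
    "corticosteroid": "H02AB07",
    "bronchodilator_other": "R03AC02",
    "peptic_ulcer": "A02BC01",
    "GI_motility": "A03FA01",
    "ACE_inhibitor": "C9A0",
}

_COUGH_PAIRS = {
    cat: [(icd, name) for icd, name, c in DEFAULT_COUGH_ROWS if c == cat.value]
    for cat in CoughCategory
}

#: Sampling weights for the cough subtype of planted Population-2 claims,
#: echoing the relative subgroup sizes seen in practice.
_P2_CATEGORY_WEIGHTS = {
    CoughCategory.OTHER: 0.55,
    CoughCategory.CVA: 0.39,
    CoughCategory.ATOPIC_ALLERGIC: 0.04,
    CoughCategory.INFECTION: 0.01,
    CoughCategory.POSTINFECTIOUS: 0.01,
}


class SimulationConfig(BaseModel):
    """Study-condition parameters of the generator.

    Demographic defaults reproduce the source cohort (mean age 43.7 ± 12.2
    years at inclusion, 61.8% women); annual attrition defaults to the
    database provider's ~14%/year estimate; facility-size weights follow the
    observed 69.9 / 8.7 / 21.4 split.  Cough-category and disease rates are
    per-consultation and per-beneficiary probabilities respectively.
    """

    n_beneficiaries: int = Field(ge=0)
    female_fraction: float = Field(default=0.618, ge=0.0, le=1.0)
    age_mean: float = 43.7
    age_sd: float = Field(default=12.2, ge=0.0)
    annual_attrition: float = Field(default=0.14, ge=0.0, le=1.0)
    monthly_consult_prob: float = Field(default=0.25, ge=0.0, le=1.0)
    cough_category_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "CHRONIC": 0.010,
            "INFECTION": 0.001,
            "ATOPIC_ALLERGIC": 0.002,
            "CVA": 0.008,
            "POSTINFECTIOUS": 0.001,
            "OTHER": 0.012,
        }
    )
    disease_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "ARNI": 0.50,
            "asthma": 0.40,
            "GERD": 0.14,
            "paranasal_sinusitis": 0.12,
            "CAID": 0.08,
            "chronic_rhinitis": 0.026,
            "postnasal_drip": 0.008,
            "vocal_cord_dysfunction": 0.012,
            "emphysema": 0.008,
            "nasal_polyps": 0.001,
        }
    )
    disease_doc_prob: float = Field(default=0.4, ge=0.0, le=1.0)
    med_class_given_condition: dict[str, float] = Field(
        default_factory=lambda: {
            "central_antitussive": 0.25,
            "expectorant": 0.50,
            "antiallergic": 0.50,
            "antimicrobial_restricted": 0.30,
            "ICS_LABA": 0.50,
            "herbal": 0.20,
            "corticosteroid": 0.20,
            "bronchodilator_other": 0.30,
            "peptic_ulcer": 0.50,
            "GI_motility": 0.15,
        }
    )
    organic_respiratory_rate: float = Field(default=0.005, ge=0.0, le=1.0)
    cancer_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    ace_user_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    facility_weights: tuple[float, float, float] = (0.699, 0.087, 0.214)
    planted_p1: int = Field(default=0, ge=0)
    planted_p2: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        for mapping in (
            self.cough_category_rates,
            self.disease_rates,
            self.med_class_given_condition,
        ):
            for key, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of range for {key!r}: {p}")
        if self.planted_p1 + self.planted_p2 > self.n_beneficiaries:
            raise ValueError("planted counts exceed n_beneficiaries")
        if abs(sum(self.facility_weights) - 1.0) > 1e-9:
            raise ValueError("facility_weights must sum to 1")
        return self


@dataclass
class GroundTruth:
    """Planted labels and generator-internal state, one row per beneficiary.

    Columns: beneficiary_id, label (P1 / P2 / non-case), index_ym (intended
    index month, empty for non-cases), subgroups (|-joined categories for
    planted P2), dropout_ym (first month no longer enrolled, empty if
    enrolled through the whole observation period).
    """

    table: pd.DataFrame

    def planted(self, label: str) -> pd.DataFrame:
        return self.table[self.table["label"] == label]


def monthly_dropout_prob(annual_attrition: float) -> float:
    """Per-month leaving probability with 1-(1-p)^12 = annual rate."""
    return 1.0 - (1.0 - annual_attrition) ** (1.0 / 12.0)


def generate(
    config: SimulationConfig,
    seed: int,
    periods: StudyPeriods | None = None,
) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate one claims bundle plus ground truth, deterministic in seed."""
    periods = periods or StudyPeriods()
    rng = np.random.default_rng(seed)
    n = config.n_beneficiaries
    T = periods.n_months
    start = periods.study_start.value
    sel_lo = periods.selection_start.value - start
    sel_hi = periods.selection_end.value - start

    ids = np.array([f"B{i:06d}" for i in range(n)])
    n_p1, n_p2 = config.planted_p1, config.planted_p2
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[: n_p1 + n_p2] = True

    # Demographics.  Ages are years at the study start, truncated to the
    # database's under-75 working-age profile; planted members are forced
    # adult so the age screen never removes them.
    gender = np.where(rng.random(n) < config.female_fraction, "female", "male")
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 1.0, 74.0)
    ages[planted_mask] = np.clip(ages[planted_mask], 22.0, 74.0)
    birth_m = start - (ages * 12).astype(np.int64) - rng.integers(0, 12, size=n)

    facility = rng.choice(
        np.array(["beds_1_19", "beds_20_199", "beds_200_plus"]),
        size=n,
        p=np.asarray(config.facility_weights, dtype=float),
    )

    # Enrolment: geometric number of enrolled months from the study start.
    p_month = monthly_dropout_prob(config.annual_attrition)
    if p_month > 0.0:
        enrolled_months = rng.geometric(p_month, size=n)
    else:
        enrolled_months = np.full(n, T + 1, dtype=np.int64)

    # Planted patterns.
    truth_label = np.array(["non-case"] * n, dtype=object)
    truth_index = np.array([""] * n, dtype=object)
    truth_subgroups = np.array([""] * n, dtype=object)
    planted_dx: list[tuple[str, int, str, str]] = []  # (id, month, icd, name)

    def _ensure_enrolled_through(i: int, month_offset: int) -> None:
        enrolled_months[i] = max(enrolled_months[i], month_offset + 1)

    for i in range(n_p1):
        idx = int(rng.integers(sel_lo, sel_hi + 1))
        truth_label[i] = "P1"
        truth_index[i] = str(YearMonth(start + idx))
        icd, name = _COUGH_PAIRS[CoughCategory.CHRONIC][0]
        planted_dx.append((ids[i], idx, icd, name))
        planted_dx.append((ids[i], idx - 6, *_NEUTRAL_CODE))
        post = idx + int(rng.integers(1, 13))
        planted_dx.append((ids[i], post, *_NEUTRAL_CODE))
        _ensure_enrolled_through(i, post)

    p2_cats = list(_P2_CATEGORY_WEIGHTS)
    p2_weights = np.array([_P2_CATEGORY_WEIGHTS[c] for c in p2_cats])
    p2_weights = p2_weights / p2_weights.sum()
    for i in range(n_p1, n_p1 + n_p2):
        idx = int(rng.integers(sel_lo, sel_hi + 1))
        s = idx - int(rng.integers(3, 6))  # window start in [idx-5, idx-3]
        e1 = s + int(rng.integers(0, 2))  # two distinct eval months
        e2 = e1 + 1 + int(rng.integers(0, s + 2 - e1))
        cats = rng.choice(len(p2_cats), size=3, p=p2_weights)
        months = (e1, e2, idx)
        sub: set[str] = set()
        for m_off, ci in zip(months, cats):
            cat = p2_cats[int(ci)]
            pairs = _COUGH_PAIRS[cat]
            icd, name = pairs[int(rng.integers(0, len(pairs)))]
            planted_dx.append((ids[i], m_off, icd, name))
            sub.add(cat.value)
        truth_label[i] = "P2"
        truth_index[i] = str(YearMonth(start + idx))
        truth_subgroups[i] = "|".join(sorted(sub))
        planted_dx.append((ids[i], idx - 6, *_NEUTRAL_CODE))
        post = idx + int(rng.integers(1, 13))
        planted_dx.append((ids[i], post, *_NEUTRAL_CODE))
        _ensure_enrolled_through(i, post)

    active = np.arange(T)[None, :] < enrolled_months[:, None]
    consult = active & (rng.random((n, T)) < config.monthly_consult_prob)

    dx_id: list[np.ndarray] = []
    dx_month: list[np.ndarray] = []
    dx_icd: list[np.ndarray] = []
    dx_name: list[np.ndarray] = []

    def _emit_dx(mask: np.ndarray, icd: str, name: str) -> None:
        bi, bt = np.nonzero(mask)
        if len(bi) == 0:
            return
        dx_id.append(ids[bi])
        dx_month.append(bt)
        dx_icd.append(np.full(len(bi), icd, dtype=object))
        dx_name.append(np.full(len(bi), name, dtype=object))

    # Cough claims.  Planted members never emit random chronic-cough claims
    # (it would shift a planted index or break the Population-2 definition).
    any_cough = np.zeros((n, T), dtype=bool)
    for cat in CoughCategory:
        rate = config.cough_category_rates.get(cat.value, 0.0)
        emit = consult & (rng.random((n, T)) < rate)
        if cat is CoughCategory.CHRONIC:
            emit[planted_mask] = False
        if not emit.any():
            continue
        any_cough |= emit
        pairs = _COUGH_PAIRS[cat]
        if len(pairs) == 1:
            _emit_dx(emit, *pairs[0])
        else:
            bi, bt = np.nonzero(emit)
            choice = rng.integers(0, len(pairs), size=len(bi))
            for k, (icd, name) in enumerate(pairs):
                sel = choice == k
                if sel.any():
                    dx_id.append(ids[bi[sel]])
                    dx_month.append(bt[sel])
                    dx_icd.append(np.full(int(sel.sum()), icd, dtype=object))
                    dx_name.append(np.full(int(sel.sum()), name, dtype=object))

    # Cough-related disease claims.
    owned: dict[str, np.ndarray] = {}
    for disease, (icd, name) in _DISEASE_CODES.items():
        owned_d = rng.random(n) < config.disease_rates.get(disease, 0.0)
        owned[disease] = owned_d
        doc = consult & owned_d[:, None] & (rng.random((n, T)) < config.disease_doc_prob)
        _emit_dx(doc, icd, name)

    # Exclusion-trigger claims; never on planted members.
    for key, rate in (
        ("organic_respiratory", config.organic_respiratory_rate),
        ("cancer", config.cancer_rate),
    ):
        flag = rng.random(n) < rate
        flag[planted_mask] = False
        doc = consult & flag[:, None] & (rng.random((n, T)) < 0.3)
        _emit_dx(doc, *_EXCL_CODES[key])

    # Add planted cough claims and anchors on top of the background.
    for b, m_off, icd, name in planted_dx:
        dx_id.append(np.array([b], dtype=object))
        dx_month.append(np.array([m_off]))
        dx_icd.append(np.array([icd], dtype=object))
        dx_name.append(np.array([name], dtype=object))

    # Prescriptions: per-class condition masks, days uniform in the month.
    conditions = {
        "central_antitussive": lambda: any_cough,
        "expectorant": lambda: any_cough,
        "herbal": lambda: any_cough,
        "antiallergic": lambda: consult
        & (owned["ARNI"] | owned["chronic_rhinitis"])[:, None],
        "ICS_LABA": lambda: consult & owned["asthma"][:, None],
        "bronchodilator_other": lambda: consult
        & (owned["asthma"] | owned["CAID"])[:, None],
        "corticosteroid": lambda: consult & (owned["asthma"] | owned["CAID"])[:, None],
        "antimicrobial_restricted": lambda: (
            consult & owned["paranasal_sinusitis"][:, None]
        )
        | any_cough,
        "peptic_ulcer": lambda: consult & owned["GERD"][:, None],
        "GI_motility": lambda: consult & owned["GERD"][:, None],
    }
    rx_id: list[np.ndarray] = []
    rx_day: list[np.ndarray] = []
    rx_atc: list[np.ndarray] = []
    for cls, cond in conditions.items():
        p = config.med_class_given_condition.get(cls, 0.0)
        emit = cond() & (rng.random((n, T)) < p)
        bi, bt = np.nonzero(emit)
        if len(bi) == 0:
            continue
        rx_id.append(ids[bi])
        rx_day.append(bt * 100 + rng.integers(1, 29, size=len(bi)))
        rx_atc.append(np.full(len(bi), _ATC[cls], dtype=object))

    ace_flag = rng.random(n) < config.ace_user_rate
    ace_flag[planted_mask] = False
    ace_emit = consult & ace_flag[:, None] & (rng.random((n, T)) < 0.3)
    bi, bt = np.nonzero(ace_emit)
    if len(bi):
        rx_id.append(ids[bi])
        rx_day.append(bt * 100 + rng.integers(1, 29, size=len(bi)))
        rx_atc.append(np.full(len(bi), _ATC["ACE_inhibitor"], dtype=object))

    # Assemble tables in deterministic sorted order.
    beneficiaries = pd.DataFrame(
        {"id": ids, "birth_m": birth_m, "gender": gender}
    ).sort_values("id", kind="stable", ignore_index=True)

    if dx_id:
        diagnoses = pd.DataFrame(
            {
                "beneficiary_id": np.concatenate(dx_id),
                "month": np.concatenate(dx_month) + start,
                "icd10": np.concatenate(dx_icd),
                "standard_name": np.concatenate(dx_name),
            }
        )
        fac_of = dict(zip(ids, facility))
        diagnoses["facility_size"] = diagnoses["beneficiary_id"].map(fac_of)
        diagnoses = diagnoses.drop_duplicates().sort_values(
            ["beneficiary_id", "month", "icd10", "standard_name"],
            kind="stable",
            ignore_index=True,
        )
    else:
        from .records import empty_diagnoses

        diagnoses = empty_diagnoses()

    if rx_id:
        packed = np.concatenate(rx_day)
        months_off = packed // 100
        days = packed % 100
        abs_month = months_off + start
        dates = pd.to_datetime(
            {
                "year": abs_month // 12,
                "month": abs_month % 12 + 1,
                "day": days,
            }
        )
        prescriptions = pd.DataFrame(
            {
                "beneficiary_id": np.concatenate(rx_id),
                "date": dates,
                "atc": np.concatenate(rx_atc),
            }
        ).sort_values(
            ["beneficiary_id", "date", "atc"], kind="stable", ignore_index=True
        )
    else:
        from .records import empty_prescriptions

        prescriptions = empty_prescriptions()

    dropout_ym = [
        str(YearMonth(start + int(k))) if k <= T else ""
        for k in enrolled_months
    ]
    truth = GroundTruth(
        pd.DataFrame(
            {
                "beneficiary_id": ids,
                "label": truth_label,
                "index_ym": truth_index,
                "subgroups": truth_subgroups,
                "dropout_ym": dropout_ym,
            }
        ).sort_values("beneficiary_id", kind="stable", ignore_index=True)
    )
    bundle = ClaimsBundle(beneficiaries, diagnoses, prescriptions)
    if n:
        bundle.validate()
    return bundle, truth


# --- hand-built fixtures ----------------------------------------------------

FIXTURE_NAMES = (
    "single-P1",
    "single-P2-minimal",
    "overlap-case",
    "excluded-by-ACE",
    "excluded-by-age",
    "short-history",
    "no-postindex-claim",
)


def _mini_bundle(birth: YearMonth, dx_rows, rx_rows=()) -> ClaimsBundle:
    beneficiaries = pd.DataFrame(
        {"id": ["F000001"], "birth_m": [birth.value], "gender": ["female"]}
    )
    diagnoses = pd.DataFrame(
        {
            "beneficiary_id": ["F000001"] * len(dx_rows),
            "month": [m.value for m, _, _ in dx_rows],
            "icd10": [icd for _, icd, _ in dx_rows],
            "standard_name": [name for _, _, name in dx_rows],
            "facility_size": ["beds_1_19"] * len(dx_rows),
        }
    )
    if rx_rows:
        prescriptions = pd.DataFrame(
            {
                "beneficiary_id": ["F000001"] * len(rx_rows),
                "date": pd.to_datetime([d for d, _ in rx_rows]),
                "atc": [atc for _, atc in rx_rows],
            }
        )
    else:
        from .records import empty_prescriptions

        prescriptions = empty_prescriptions()
    return ClaimsBundle(beneficiaries, diagnoses, prescriptions).validate()


def make_fixture(name: str) -> ClaimsBundle:
    """Minimal hand-built bundles with documented expected outcomes.

    * ``single-P1`` — one chronic-cough claim 2018-03 with history and
      post-index anchors; expected: Population 1, index 2018-03.
    * ``single-P2-minimal`` — cough codes in exactly months 2018-01, 2018-02
      and 2018-04; expected: Population 2, index 2018-04.
    * ``overlap-case`` — the Population-2 pattern plus a chronic-cough claim;
      expected: Population 1 (precedence).
    * ``excluded-by-ACE`` — single-P1 plus one C9A prescription; excluded.
    * ``excluded-by-age`` — single-P1 born 1999-06 (18 at index); excluded.
    * ``short-history`` — first-ever claim two months before index; excluded.
    * ``no-postindex-claim`` — nothing after the index month; excluded.
    """
    chronic = ("R05", "chronic cough")
    dry = ("R05", "dry cough")
    cva = ("J45.9", "cough-variant asthma")
    neutral = _NEUTRAL_CODE
    adult = ym(1980, 5)

    if name == "single-P1":
        return _mini_bundle(
            adult,
            [
                (ym(2017, 9), *neutral),
                (ym(2018, 3), *chronic),
                (ym(2018, 8), *neutral),
            ],
        )
    if name == "single-P2-minimal":
        return _mini_bundle(
            adult,
            [
                (ym(2017, 9), *neutral),
                (ym(2018, 1), *dry),
                (ym(2018, 2), *cva),
                (ym(2018, 4), *dry),
                (ym(2018, 8), *neutral),
            ],
        )
    if name == "overlap-case":
        return _mini_bundle(
            adult,
            [
                (ym(2017, 9), *neutral),
                (ym(2018, 1), *dry),
                (ym(2018, 2), *cva),
                (ym(2018, 3), *chronic),
                (ym(2018, 4), *dry),
                (ym(2018, 8), *neutral),
            ],
        )
    if name == "excluded-by-ACE":
        return _mini_bundle(
            adult,
            [
                (ym(2017, 9), *neutral),
                (ym(2018, 3), *chronic),
                (ym(2018, 8), *neutral),
            ],
            rx_rows=[("2020-02-10", "C9A0")],
        )
    if name == "excluded-by-age":
        return _mini_bundle(
            ym(1999, 6),
            [
                (ym(2017, 9), *neutral),
                (ym(2018, 3), *chronic),
                (ym(2018, 8), *neutral),
            ],
        )
    if name == "short-history":
        return _mini_bundle(
            adult,
            [
                (ym(2018, 1), *neutral),
                (ym(2018, 3), *chronic),
                (ym(2018, 8), *neutral),
            ],
        )
    if name == "no-postindex-claim":
        return _mini_bundle(
            adult,
            [
                (ym(2017, 9), *neutral),
                (ym(2018, 3), *chronic),
            ],
        )
    raise ValueError(f"unknown fixture name: {name!r}; choose from {FIXTURE_NAMES}")
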