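"""Two-population chronic-cough cohort identification.

The phenotype is temporal, built on month-resolution diagnosis claims:

* **Population 1** — beneficiaries with at least one claim carrying the
  explicit chronic-cough code pair during the selection period.  The index
  month is the first such month.
* **Population 2** — beneficiaries without any selection-period chronic-cough
  claim, but with other diagnostic cough codes in at least two distinct months
  of a three-consecutive-month evaluation window, followed by at least one
  further cough code in the subsequent three-month post-evaluation window.
  The index month is the earliest post-evaluation-window month carrying a
  cough code, and must fall inside the selection period.  At monthly
  resolution this pattern guarantees a cough spanning more than eight weeks.

Anyone eligible for both populations is assigned to Population 1, so the two
are mutually exclusive.  Eligibility screening then removes beneficiaries who
are under 20 at the index month, ever received an ACE inhibitor (a classic
iatrogenic cause of cough), carry an organic respiratory disease or cancer
code, lack six months of pre-index history, or have no claim at all in the
twelve post-index months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebooks import (
    Codebooks,
    CoughCategory,
    CoughCodebook,
    DiseaseLabel,
    MedicationClass,
    POP2_CATEGORIES,
)
from .months import YearMonth
from .records import ClaimsBundle, StudyPeriods, rx_months

EXCLUSION_REASONS = (
    "under_20",
    "ace_inhibitor",
    "organic_respiratory_or_cancer",
    "insufficient_history",
    "no_postindex_claim",
    "no_qualifying_cough",
)

#: Screening reasons applied after the cough criteria are met (flow step 4).
_ELIGIBILITY_REASONS = frozenset(
    {"ace_inhibitor", "organic_respiratory_or_cancer", "insufficient_history", "no_postindex_claim"}
)


@dataclass(frozen=True)
class EvaluationWindow:
    """A qualifying 3-month evaluation window and its post-evaluation window."""

    start: YearMonth
    eval_cough_months: frozenset
    post_cough_months: frozenset

    @property
    def post_start(self) -> YearMonth:
        return self.start + 3


@dataclass(frozen=True)
class CohortAssignment:
    beneficiary_id: str
    population: str  # "P1" | "P2"
    index_month: YearMonth
    subgroups: frozenset  # of CoughCategory; empty for P1
    qualifying_window: EvaluationWindow | None
    age_at_index: int
    gender: str
    facility_size: str


@dataclass(frozen=True)
class ExclusionReport:
    beneficiary_id: str
    reasons: frozenset


@dataclass
class CohortOptions:
    """Tunable conventions of the identification algorithm.

    subgroup_window
        ``"to_index"`` (default): subgroup membership uses cough claims from
        the qualifying window start through the index month inclusive.
        ``"full_window"``: uses the whole evaluation period plus
        post-evaluation window regardless of the index month.
    """

    subgroup_window: str = "to_index"


@dataclass
class CohortResult:
    assignments: dict  # beneficiary_id -> CohortAssignment
    exclusions: dict  # beneficiary_id -> ExclusionReport
    flow: dict  # ordered step name -> count

    @property
    def p1_ids(self):
        return {b for b, a in self.assignments.items() if a.population == "P1"}

    @property
    def p2_ids(self):
        return {b for b, a in self.assignments.items() if a.population == "P2"}

    def subgroup_ids(self, category: CoughCategory) -> set:
        return {
            b for b, a in self.assignments.items()
            if a.population == "P2" and category in a.subgroups
        }


def classify_cough_claim(icd10: str, standard_name: str, codebook: CoughCodebook):
    """Cough category of one diagnosis claim, or None for unlisted pairs."""
    return codebook.category(icd10, standard_name)


def _cough_month_maps(claims: pd.DataFrame, codebook: CoughCodebook):
    """(chronic month set, {month -> set of Population-2 categories})."""
    chronic: set[int] = set()
    p2: dict[int, set] = {}
    for month, icd10, name in zip(claims["month"], claims["icd10"], claims["standard_name"]):
        cat = codebook.category(icd10, name)
        if cat is None:
            continue
        if cat is CoughCategory.CHRONIC:
            chronic.add(int(month))
        else:
            p2.setdefault(int(month), set()).add(cat)
    return chronic, p2


def find_pop1_index(claims: pd.DataFrame, codebook: CoughCodebook, periods: StudyPeriods):
    """Earliest selection-period month with a chronic-cough claim, else None."""
    chronic, _ = _cough_month_maps(claims, codebook)
    eligible = [m for m in chronic
                if periods.selection_start.value <= m <= periods.selection_end.value]
    return YearMonth(min(eligible)) if eligible else None


def _pop2_scan(p2_months: set, periods: StudyPeriods):
    """First qualifying (index, window) over calendar-ordered window starts."""
    if len(p2_months) < 3:
        return None
    lo, hi = periods.study_start.value, periods.selection_end.value
    for s in range(lo, hi + 1):
        eval_m = p2_months.intersection((s, s + 1, s + 2))
        if len(eval_m) < 2:
            continue
        post_m = p2_months.intersection((s + 3, s + 4, s + 5))
        if not post_m:
            continue
        idx = min(post_m)
        if not periods.selection_start.value <= idx <= periods.selection_end.value:
            continue
        window = EvaluationWindow(
            start=YearMonth(s),
            eval_cough_months=frozenset(YearMonth(m) for m in eval_m),
            post_cough_months=frozenset(YearMonth(m) for m in post_m),
        )
        return YearMonth(idx), window
    return None


def find_pop2_index(claims: pd.DataFrame, codebook: CoughCodebook, periods: StudyPeriods):
    """First qualifying evaluation window and its index month, else None.

    Candidate windows are scanned in calendar order from the study start; the
    earliest qualifying window wins and the index month is the earliest
    post-evaluation-window month carrying a Population-2 cough code.  The
    index month must lie inside the selection period.  Chronic-cough claims
    never contribute: Population-1 precedence is enforced by the caller.
    """
    _, p2 = _cough_month_maps(claims, codebook)
    hit = _pop2_scan(set(p2), periods)
    if hit is None:
        return None
    return hit  # (index_month, window)


def age_at(birth_m: int, month: int) -> int:
    """Completed years between a birth month and a reference month."""
    return (month - birth_m) // 12


def screen_eligibility(
    birth_m: int,
    index_month: int,
    all_claim_months: set,
    has_ace: bool,
    has_excl_disease: bool,
) -> frozenset:
    """Exclusion reasons for a candidate member at a candidate index month.

    ``all_claim_months`` covers diagnosis and prescription claims of any kind;
    database enrolment spells are not recorded, so "documented in the database
    for six months before index" is proxied by the first-ever claim month.
    """
    reasons = set()
    if age_at(birth_m, index_month) < 20:
        reasons.add("under_20")
    if has_ace:
        reasons.add("ace_inhibitor")
    if has_excl_disease:
        reasons.add("organic_respiratory_or_cancer")
    if not all_claim_months or min(all_claim_months) > index_month - 6:
        reasons.add("insufficient_history")
    if not any(index_month + 1 <= m <= index_month + 12 for m in all_claim_months):
        reasons.add("no_postindex_claim")
    return frozenset(reasons)


def assign_subgroups(
    window: EvaluationWindow,
    index_month: YearMonth,
    p2_by_month: dict,
    options: CohortOptions | None = None,
) -> frozenset:
    """Cough subtype set of a Population-2 member.

    Categories of all Population-2 cough claims from the qualifying window
    start through the index month (inclusive); with the ``full_window``
    option, through the end of the post-evaluation window instead.
    """
    options = options or CohortOptions()
    lo = window.start.value
    if options.subgroup_window == "full_window":
        hi = window.start.value + 5
    else:
        hi = index_month.value
    cats: set = set()
    for m, cs in p2_by_month.items():
        if lo <= m <= hi:
            cats.update(cs)
    return frozenset(cats)


_FACILITY_RANK = {"beds_1_19": 0, "beds_20_199": 1, "beds_200_plus": 2}


def _facility_at_index(rows, index_month: int) -> str:
    """Mode of facility size over index-month claims; ties toward larger."""
    counts: dict[str, int] = {}
    for m, fs in rows:
        if m == index_month and fs in _FACILITY_RANK:
            counts[fs] = counts.get(fs, 0) + 1
    if not counts:
        return "unknown"
    return max(counts, key=lambda fs: (counts[fs], _FACILITY_RANK[fs]))


def _prefix_map(codes, lookup):
    """Vectorise a longest-prefix codebook over a column's unique codes."""
    uniq = pd.unique(codes)
    return {c: lookup(c) for c in uniq}


def build_cohort(
    bundle: ClaimsBundle,
    codebooks: Codebooks,
    periods: StudyPeriods,
    options: CohortOptions | None = None,
) -> CohortResult:
    """Run the full identification algorithm over a claims bundle.

    Returns assignments (one population per eligible beneficiary, Population 1
    taking precedence), exclusion reports for beneficiaries with cough claims
    who did not enter the cohort, and the participant-flow counts.
    """
    options = options or CohortOptions()
    ben = bundle.beneficiaries
    dx = bundle.diagnoses
    rx = bundle.prescriptions

    birth = dict(zip(ben["id"], (int(v) for v in ben["birth_m"])))
    gender = dict(zip(ben["id"], ben["gender"]))

    # Claim months of any kind, per beneficiary.
    claim_months: dict[str, set] = {b: set() for b in birth}
    for b, m in zip(dx["beneficiary_id"], dx["month"]):
        claim_months[b].add(int(m))
    if len(rx):
        for b, m in zip(rx["beneficiary_id"], rx_months(rx)):
            claim_months[b].add(int(m))

    # Exclusion screens over the whole study period.
    excl_label = _prefix_map(dx["icd10"], codebooks.disease.label) if len(dx) else {}
    excl_ids = {
        b for b, icd in zip(dx["beneficiary_id"], dx["icd10"])
        if (lbl := excl_label.get(icd)) is not None and lbl.value.startswith("EXCL_")
    }
    ace_class = _prefix_map(rx["atc"], codebooks.medication.label) if len(rx) else {}
    ace_ids = {
        b for b, atc in zip(rx["beneficiary_id"], rx["atc"])
        if ace_class.get(atc) is MedicationClass.ACE_INHIBITOR
    }

    # Cough claim months and facility-size rows per beneficiary, one pass.
    chronic_months: dict[str, set] = {}
    p2_by_month: dict[str, dict] = {}
    fac_rows: dict[str, list] = {}
    for b, m, icd, name, fs in zip(
        dx["beneficiary_id"], dx["month"], dx["icd10"], dx["standard_name"],
        dx["facility_size"],
    ):
        fac_rows.setdefault(b, []).append((int(m), fs))
        cat = codebooks.cough.category(icd, name)
        if cat is None:
            continue
        if cat is CoughCategory.CHRONIC:
            chronic_months.setdefault(b, set()).add(int(m))
        else:
            p2_by_month.setdefault(b, {}).setdefault(int(m), set()).add(cat)

    sel_lo, sel_hi = periods.selection_start.value, periods.selection_end.value

    assignments: dict[str, CohortAssignment] = {}
    exclusions: dict[str, ExclusionReport] = {}

    n_any_claim = sum(1 for ms in claim_months.values() if ms)
    adults_sel = {
        b for b, ms in claim_months.items()
        if any(sel_lo <= m <= sel_hi for m in ms) and age_at(birth[b], sel_hi) >= 20
    }
    cough_sel = {
        b for b in adults_sel
        if any(sel_lo <= m <= sel_hi for m in chronic_months.get(b, ()))
        or any(sel_lo <= m <= sel_hi for m in p2_by_month.get(b, ()))
    }

    n_criteria_met = 0
    n_excluded = 0
    candidates = sorted(set(chronic_months) | set(p2_by_month))
    for b in candidates:
        sel_chronic = [m for m in chronic_months.get(b, ()) if sel_lo <= m <= sel_hi]
        if sel_chronic:
            population, index_m, window = "P1", min(sel_chronic), None
        else:
            hit = _pop2_scan(set(p2_by_month.get(b, ())), periods)
            if hit is None:
                if b in cough_sel:
                    exclusions[b] = ExclusionReport(b, frozenset({"no_qualifying_cough"}))
                continue
            index_ym, window = hit
            population, index_m = "P2", index_ym.value

        reasons = screen_eligibility(
            birth[b], index_m, claim_months[b], b in ace_ids, b in excl_ids
        )
        if "under_20" in reasons:
            exclusions[b] = ExclusionReport(b, reasons)
            continue
        n_criteria_met += 1
        if reasons:
            n_excluded += 1
            exclusions[b] = ExclusionReport(b, reasons)
            continue

        if population == "P2":
            subgroups = assign_subgroups(
                window, YearMonth(index_m), p2_by_month[b], options
            )
        else:
            subgroups = frozenset()
        assignments[b] = CohortAssignment(
            beneficiary_id=b,
            population=population,
            index_month=YearMonth(index_m),
            subgroups=subgroups,
            qualifying_window=window,
            age_at_index=age_at(birth[b], index_m),
            gender=gender[b],
            facility_size=_facility_at_index(fac_rows.get(b, ()), index_m),
        )

    flow = {
        "any_claim": n_any_claim,
        "adults_with_selection_claim": len(adults_sel),
        "any_cough_code": len(cough_sel),
        "criteria_met": n_criteria_met,
        "excluded_eligibility": n_excluded,
        "enrolled": len(assignments),
    }
    return CohortResult(assignments=assignments, exclusions=exclusions, flow=flow)
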