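"""Table assembly, flow reconciliation and diagnosis-persistence partition.

Everything here is descriptive: counts, denominators and percentages rounded
half-up to one decimal.  No statistical hypotheses are formulated or tested.

The persistence partition classifies each enrolled member by what remains of
their cough coding in months index+10 .. index+12: members still carrying a
code of their original category are *retained*; members with only other
cough-category codes moved to *another cough code*; members evaluable there
only through a cough-related-disease code hold a *disease code only*; and
members with no qualifying diagnosis claim at all *left the cohort* (resolved
cough, database attrition, or care without a cough-related claim).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .codebooks import (
    CLASSES_OF_INTEREST,
    COUGH_RELATED_DISEASES,
    Codebooks,
    CoughCategory,
    MedicationClass,
)
from .cohort import CohortResult
from .extract import (
    TIME_POINTS,
    cough_categories_in,
    diseases_in,
    evaluable_at_m10_12,
    medication_summary,
    member_cough_sets,
    rx_by_member,
)
from .records import ClaimsBundle, StudyPeriods

TABLE_IDS = ("T2", "T3", "T4", "T5", "T6", "T7", "Fig3", "Fig4", "flow")


def percent(count: int, denominator: int):
    """``100*count/denominator`` rounded half-up to one decimal.

    Returns None (an explicit undefined marker) for a zero denominator.
    """
    if denominator == 0:
        return None
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_percent(count: int, denominator: int) -> str:
    p = percent(count, denominator)
    return "—" if p is None else f"{p:.1f}%"


def flow_reconciliation(steps) -> list:
    """Remaining count after each (label, excluded) attrition step.

    ``steps`` is ``(initial_count, [(label, n_excluded), ...])``; returns
    ``[(label, excluded, remaining), ...]`` and raises on a negative
    remainder.
    """
    initial, exclusions = steps
    remaining = int(initial)
    out = [("start", 0, remaining)]
    for label, excluded in exclusions:
        remaining -= int(excluded)
        if remaining < 0:
            raise ValueError(f"flow step {label!r} leaves a negative remainder")
        out.append((label, int(excluded), remaining))
    return out


@dataclass
class PersistencePartition:
    label: str
    enrolled: int
    evaluable: int
    retained_original: int
    other_cough: int
    disease_only: int
    left_cohort: int

    def check(self) -> "PersistencePartition":
        if self.retained_original + self.other_cough + self.disease_only != self.evaluable:
            raise ValueError("persistence partition does not sum to the evaluable count")
        if self.evaluable + self.left_cohort != self.enrolled:
            raise ValueError("evaluable + left_cohort must equal enrolled")
        return self


def persistence_partition(
    label: str,
    members: dict,
    evaluable: set,
    m10_12_cough_sets: dict,
    original_categories,
) -> PersistencePartition:
    """Priority classification of each enrolled member at months 10-12.

    original category present -> retained; else any cough category ->
    other_cough; else disease code only (guaranteed by evaluability) ->
    disease_only; not evaluable -> left_cohort.
    """
    original = frozenset(original_categories)
    retained = other = disease_only = left = 0
    for b in members:
        if b not in evaluable:
            left += 1
            continue
        cats = m10_12_cough_sets.get(b, set())
        if cats & original:
            retained += 1
        elif cats:
            other += 1
        else:
            disease_only += 1
    return PersistencePartition(
        label=label,
        enrolled=len(members),
        evaluable=len(evaluable),
        retained_original=retained,
        other_cough=other,
        disease_only=disease_only,
        left_cohort=left,
    ).check()


# --- population subsets -----------------------------------------------------

#: Display order of cough categories in tables.
_CATEGORY_ORDER = (
    CoughCategory.CHRONIC,
    CoughCategory.INFECTION,
    CoughCategory.ATOPIC_ALLERGIC,
    CoughCategory.CVA,
    CoughCategory.POSTINFECTIOUS,
    CoughCategory.OTHER,
)

#: Original-category sets used for the persistence partition.
_ORIGINAL_CATS = {
    "P1": frozenset({CoughCategory.CHRONIC}),
    "subgroup": None,  # the subgroup's own category
}


def population_subsets(cohort: CohortResult, n_subgroups: int = 3) -> dict:
    """Analysis populations: All, P1, P2, and the largest P2 subgroups.

    Returns ``{name: (members dict, original categories or None)}`` where the
    original categories drive the persistence partition.
    """
    assignments = cohort.assignments
    p1 = {b: a for b, a in assignments.items() if a.population == "P1"}
    p2 = {b: a for b, a in assignments.items() if a.population == "P2"}
    subsets = {
        "All": (dict(assignments), None),
        "P1": (p1, frozenset({CoughCategory.CHRONIC})),
        "P2": (p2, None),
    }
    sizes = []
    for cat in _CATEGORY_ORDER[1:]:
        ids = {b for b, a in p2.items() if cat in a.subgroups}
        if ids:
            sizes.append((len(ids), cat, ids))
    sizes.sort(key=lambda t: -t[0])
    for _, cat, ids in sizes[:n_subgroups]:
        subsets[f"P2:{cat.value}"] = (
            {b: p2[b] for b in ids},
            frozenset({cat}),
        )
    return subsets


# --- summaries --------------------------------------------------------------

def extract_summaries(
    cohort: CohortResult,
    bundle: ClaimsBundle,
    codebooks: Codebooks,
    periods: StudyPeriods,
    time_points=TIME_POINTS,
    n_subgroups: int = 3,
) -> dict:
    """All window summaries for every analysis population, JSON-serialisable."""
    subsets = population_subsets(cohort, n_subgroups)
    dx = bundle.diagnoses
    rx = bundle.prescriptions
    all_rx = rx_by_member(rx, cohort.assignments)

    populations = {}
    for name, (members, original) in subsets.items():
        evaluable = evaluable_at_m10_12(members, dx, codebooks.cough, codebooks.disease)
        cough = {
            "index": cough_categories_in(members, "index", dx, codebooks.cough),
            "M10_12": cough_categories_in(
                members, "M10_12", dx, codebooks.cough, denominator=len(evaluable)
            ),
        }
        diseases = {
            "index": diseases_in(members, "index", dx, codebooks.disease),
            "pre_index": diseases_in(members, "pre_index", dx, codebooks.disease),
            "M10_12": diseases_in(
                members, "M10_12", dx, codebooks.disease, denominator=len(evaluable)
            ),
        }
        member_rx = {b: all_rx.get(b, []) for b in members}
        meds = {
            str(tp): medication_summary(
                members, tp, rx, codebooks.medication, member_rx=member_rx
            )
            for tp in time_points
        }
        persistence = None
        if original:
            persistence = persistence_partition(
                name,
                members,
                evaluable,
                member_cough_sets(members, "M10_12", dx, codebooks.cough),
                original,
            )
        ages = [a.age_at_index for a in members.values()]
        age_mean = float(pd.Series(ages).mean()) if ages else None
        age_sd = float(pd.Series(ages).std(ddof=1)) if len(ages) > 1 else None
        fac_counts = {
            k: sum(1 for a in members.values() if a.facility_size == k)
            for k in ("beds_1_19", "beds_20_199", "beds_200_plus", "unknown")
        }
        populations[name] = {
            "n_enrolled": len(members),
            "evaluable_m10_12": len(evaluable),
            "age_mean": age_mean,
            "age_sd": age_sd,
            "age_60_plus": sum(1 for a in members.values() if a.age_at_index >= 60),
            "gender": {
                g: sum(1 for a in members.values() if a.gender == g)
                for g in ("male", "female")
            },
            "facility": fac_counts,
            "cough": {
                k: {"counts": {c.value: n for c, n in s.counts.items()},
                    "denominator": s.denominator}
                for k, s in cough.items()
            },
            "diseases": {
                k: {"counts": {d.value: n for d, n in s.counts.items()},
                    "denominator": s.denominator}
                for k, s in diseases.items()
            },
            "medications": {
                k: {
                    "n_any": s.n_any,
                    "antitussive_alone": s.antitussive_alone,
                    "classes": {
                        c.value: {
                            "total": cc.total,
                            "with_antitussive": cc.with_antitussive,
                            "without_antitussive": cc.without_antitussive,
                        }
                        for c, cc in s.per_class.items()
                    },
                }
                for k, s in meds.items()
            },
            "persistence": None
            if persistence is None
            else {
                "enrolled": persistence.enrolled,
                "evaluable": persistence.evaluable,
                "retained_original": persistence.retained_original,
                "other_cough": persistence.other_cough,
                "disease_only": persistence.disease_only,
                "left_cohort": persistence.left_cohort,
            },
        }
    return {"populations": populations, "flow": dict(cohort.flow)}


# --- tables -----------------------------------------------------------------

@dataclass
class TableSpec:
    table_id: str
    rows: list  # list of dicts; count rows carry count/denominator/percent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _count_row(population: str, label: str, count: int, denominator: int, **extra):
    row = {
        "population": population,
        "label": label,
        "count": count,
        "denominator": denominator,
        "percent": format_percent(count, denominator),
    }
    row.update(extra)
    return row


def build_tables(summaries: dict, time_points=TIME_POINTS) -> dict:
    """Assemble every output table from the extracted window summaries.

    Raises KeyError naming the missing summary when one is absent.
    """
    pops = summaries["populations"]
    tables: dict[str, TableSpec] = {}

    def need(pop: str, key: str):
        if key not in pops[pop]:
            raise KeyError(f"population {pop!r} lacks summary {key!r} (needed for tables)")
        return pops[pop][key]

    # T2 — cough diagnoses during the index month.
    rows = []
    for pop, data in pops.items():
        c = need(pop, "cough")["index"]
        for cat in _CATEGORY_ORDER:
            rows.append(_count_row(pop, cat.value, c["counts"][cat.value], c["denominator"]))
    tables["T2"] = TableSpec("T2", rows)

    # T3 — characteristics and cough-related diseases at the index month.
    rows = []
    for pop, data in pops.items():
        n = data["n_enrolled"]
        rows.append({"population": pop, "label": "n_enrolled", "count": n,
                     "denominator": n, "percent": format_percent(n, n)})
        mean, sd = data["age_mean"], data["age_sd"]
        rows.append({
            "population": pop, "label": "age_mean_sd", "count": None,
            "denominator": None,
            "percent": "" if mean is None else f"{mean:.1f} ± {0.0 if sd is None else sd:.1f}",
        })
        rows.append(_count_row(pop, "age_60_plus", data["age_60_plus"], n))
        for g, cnt in data["gender"].items():
            rows.append(_count_row(pop, f"gender:{g}", cnt, n))
        fac = data["facility"]
        fac_known = sum(v for k, v in fac.items() if k != "unknown")
        for k in ("beds_1_19", "beds_20_199", "beds_200_plus"):
            rows.append(_count_row(pop, f"facility:{k}", fac.get(k, 0), fac_known))
        d = need(pop, "diseases")["index"]
        for disease in COUGH_RELATED_DISEASES:
            rows.append(_count_row(pop, disease.value, d["counts"][disease.value], d["denominator"]))
    tables["T3"] = TableSpec("T3", rows)

    # T4 — cough diagnoses documented at months 10 to 12.
    rows = []
    for pop, data in pops.items():
        c = need(pop, "cough")["M10_12"]
        rows.append({"population": pop, "label": "evaluable", "count": c["denominator"],
                     "denominator": data["n_enrolled"],
                     "percent": format_percent(c["denominator"], data["n_enrolled"])})
        for cat in _CATEGORY_ORDER:
            rows.append(_count_row(pop, cat.value, c["counts"][cat.value], c["denominator"]))
    tables["T4"] = TableSpec("T4", rows)

    # T5 — diseases pre-index vs months 10-12, flagging >5-point changes.
    rows = []
    for pop, data in pops.items():
        pre = need(pop, "diseases")["pre_index"]
        late = need(pop, "diseases")["M10_12"]
        for disease in COUGH_RELATED_DISEASES:
            p_pre = percent(pre["counts"][disease.value], pre["denominator"])
            p_late = percent(late["counts"][disease.value], late["denominator"])
            flagged = (
                p_pre is not None and p_late is not None and abs(p_late - p_pre) > 5.0
            )
            rows.append(_count_row(pop, disease.value, pre["counts"][disease.value],
                                   pre["denominator"], window="pre_index", flagged=flagged))
            rows.append(_count_row(pop, disease.value, late["counts"][disease.value],
                                   late["denominator"], window="M10_12", flagged=flagged))
    tables["T5"] = TableSpec("T5", rows)

    # T6 — treatments prescribed during the index month.
    rows = []
    for pop, data in pops.items():
        m = need(pop, "medications")["index"]
        n_any = m["n_any"]
        rows.append(_count_row(pop, "any_medication", n_any, data["n_enrolled"]))
        rows.append(_count_row(pop, "central_antitussives_only", m["antitussive_alone"], n_any))
        for cls in CLASSES_OF_INTEREST:
            if cls is MedicationClass.CENTRAL_ANTITUSSIVE:
                continue
            cc = m["classes"][cls.value]
            rows.append(_count_row(pop, f"{cls.value}:all", cc["total"], n_any))
            rows.append(_count_row(pop, f"{cls.value}:without_antitussive",
                                   cc["without_antitussive"], n_any))
            rows.append(_count_row(pop, f"{cls.value}:with_antitussive",
                                   cc["with_antitussive"], n_any))
    tables["T6"] = TableSpec("T6", rows)

    def need_tp(pop: str, meds: dict, tp, table: str) -> dict:
        key = str(tp)
        if key not in meds:
            raise KeyError(
                f"population {pop!r} lacks medication summary at {key!r} (needed for {table})"
            )
        return meds[key]

    # T7 — central antitussives alone across the post-index time points.
    rows = []
    for pop, data in pops.items():
        meds = need(pop, "medications")
        for tp in time_points:
            m = need_tp(pop, meds, tp, "T7")
            rows.append(_count_row(pop, f"M{tp}" if tp != "index" else "index",
                                   m["antitussive_alone"], m["n_any"]))
    tables["T7"] = TableSpec("T7", rows)

    # Fig 3 — co-prescription proportion per class, index vs month 12.
    rows = []
    for pop, data in pops.items():
        meds = need(pop, "medications")
        for cls in CLASSES_OF_INTEREST:
            if cls is MedicationClass.CENTRAL_ANTITUSSIVE:
                continue
            for tp in ("index", "12"):
                cc = need_tp(pop, meds, tp, "Fig3")["classes"][cls.value]
                rows.append(_count_row(pop, cls.value, cc["with_antitussive"],
                                       cc["total"], time_point=tp))
    tables["Fig3"] = TableSpec("Fig3", rows)

    # Fig 4 — class share of medication users per time point.
    rows = []
    for pop, data in pops.items():
        meds = need(pop, "medications")
        for tp in time_points:
            m = need_tp(pop, meds, tp, "Fig4")
            for cls in CLASSES_OF_INTEREST:
                cc = m["classes"][cls.value]
                rows.append(_count_row(pop, cls.value, cc["total"], m["n_any"],
                                       time_point=str(tp)))
    tables["Fig4"] = TableSpec("Fig4", rows)

    # Flow reconciliation.
    flow = summaries["flow"]
    steps = flow_reconciliation(
        (
            flow["criteria_met"],
            [("eligibility_exclusions", flow["excluded_eligibility"])],
        )
    )
    rows = [
        {"population": "All", "label": label, "count": excluded,
         "denominator": flow["criteria_met"], "percent": "", "remaining": remaining}
        for label, excluded, remaining in steps
    ]
    for key in ("any_claim", "adults_with_selection_claim", "any_cough_code",
                "criteria_met", "enrolled"):
        rows.append({"population": "All", "label": key, "count": flow[key],
                     "denominator": None, "percent": "", "remaining": flow[key]})
    tables["flow"] = TableSpec("flow", rows)

    return tables


def write_tables(tables: dict, out_dir, fmt: str = "tsv") -> list:
    """Write one file per table; returns the written paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for table_id, spec in tables.items():
        if fmt == "tsv":
            path = out_dir / f"{table_id}.tsv"
            spec.to_frame().to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            import json

            path = out_dir / f"{table_id}.json"
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(spec.rows, fh, indent=1)
        else:
            raise ValueError(f"unknown format: {fmt!r}")
        paths.append(path)
    return paths
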