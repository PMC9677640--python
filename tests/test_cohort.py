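import numpy as np
import pandas as pd
import pytest

from coughcohort.codebooks import CoughCategory
from coughcohort.cohort import (
    CohortOptions,
    assign_subgroups,
    build_cohort,
    classify_cough_claim,
    find_pop1_index,
    find_pop2_index,
    screen_eligibility,
)
from coughcohort.months import ym
from coughcohort.simulate import FIXTURE_NAMES, _mini_bundle, make_fixture

from _oracle import oracle_assign, random_bundle


def _dx_frame(rows):
    """rows: (YearMonth, icd10, standard_name)"""
    return pd.DataFrame(
        {
            "beneficiary_id": ["B"] * len(rows),
            "month": [m.value for m, _, _ in rows],
            "icd10": [icd for _, icd, _ in rows],
            "standard_name": [n for _, _, n in rows],
            "facility_size": ["beds_1_19"] * len(rows),
        }
    )


def test_classify_cough_claim(books):
    assert classify_cough_claim("R05", "chronic cough", books.cough) is CoughCategory.CHRONIC
    assert classify_cough_claim("J45.9", "cough-variant asthma", books.cough) is CoughCategory.CVA
    assert classify_cough_claim("J45.9", "asthma-not-in-codebook", books.cough) is None


class TestPop1Index:
    def test_earliest_selection_month_wins(self, books, periods):
        claims = _dx_frame(
            [(ym(2017, 9), "R05", "chronic cough"), (ym(2018, 1), "R05", "chronic cough")]
        )
        assert find_pop1_index(claims, books.cough, periods) == ym(2017, 9)

    def test_chronic_before_selection_start_is_ignored(self, books, periods):
        claims = _dx_frame([(ym(2017, 3), "R05", "chronic cough")])
        assert find_pop1_index(claims, books.cough, periods) is None

    def test_no_chronic_claim(self, books, periods):
        claims = _dx_frame([(ym(2018, 1), "R05", "dry cough")])
        assert find_pop1_index(claims, books.cough, periods) is None


class TestPop2Index:
    def test_minimal_qualifying_pattern(self, books, periods):
        claims = _dx_frame(
            [
                (ym(2018, 1), "R05", "dry cough"),
                (ym(2018, 2), "R05", "dry cough"),
                (ym(2018, 4), "R05", "dry cough"),
            ]
        )
        index, window = find_pop2_index(claims, books.cough, periods)
        assert index == ym(2018, 4)
        # eval cough months of the first qualifying window
        assert {str(m) for m in window.eval_cough_months} == {"2018-01", "2018-02"}

    def test_no_post_window_code(self, books, periods):
        claims = _dx_frame(
            [(ym(2018, 1), "R05", "dry cough"), (ym(2018, 3), "R05", "dry cough")]
        )
        assert find_pop2_index(claims, books.cough, periods) is None

    def test_same_month_codes_do_not_qualify(self, books, periods):
        claims = _dx_frame(
            [
                (ym(2018, 1), "R05", "dry cough"),
                (ym(2018, 1), "R05", "wet cough"),
                (ym(2018, 1), "J45.9", "cough-variant asthma"),
            ]
        )
        assert find_pop2_index(claims, books.cough, periods) is None

    def test_three_consecutive_months_qualify(self, books, periods):
        """Any 3-consecutive-month evaluation period may precede the first
        cough month, so codes in m, m+1, m+2 qualify with index m+2."""
        claims = _dx_frame(
            [
                (ym(2018, 2), "R05", "dry cough"),
                (ym(2018, 3), "R05", "dry cough"),
                (ym(2018, 4), "R05", "dry cough"),
            ]
        )
        index, window = find_pop2_index(claims, books.cough, periods)
        assert index == ym(2018, 4)

    def test_index_must_fall_in_selection_period(self, books, periods):
        # pattern ends before the selection period opens
        claims = _dx_frame(
            [
                (ym(2017, 1), "R05", "dry cough"),
                (ym(2017, 2), "R05", "dry cough"),
                (ym(2017, 4), "R05", "dry cough"),
            ]
        )
        assert find_pop2_index(claims, books.cough, periods) is None

    def test_chronic_codes_never_count_toward_pattern(self, books, periods):
        claims = _dx_frame(
            [
                (ym(2018, 1), "R05", "chronic cough"),
                (ym(2018, 2), "R05", "chronic cough"),
                (ym(2018, 4), "R05", "chronic cough"),
            ]
        )
        assert find_pop2_index(claims, books.cough, periods) is None


class TestScreening:
    def test_age_under_20(self):
        birth = ym(1999, 6).value
        index = ym(2018, 5).value
        reasons = screen_eligibility(birth, index, {index - 7, index + 2}, False, False)
        assert reasons == {"under_20"}

    def test_ace_and_exclusion_disease(self):
        birth = ym(1980, 1).value
        index = ym(2018, 5).value
        months = {index - 7, index + 2}
        assert screen_eligibility(birth, index, months, True, False) == {"ace_inhibitor"}
        assert screen_eligibility(birth, index, months, False, True) == {
            "organic_respiratory_or_cancer"
        }

    def test_short_history_and_missing_postindex(self):
        birth = ym(1980, 1).value
        index = ym(2018, 5).value
        assert screen_eligibility(birth, index, {index - 2, index + 1}, False, False) == {
            "insufficient_history"
        }
        assert screen_eligibility(birth, index, {index - 6, index + 13}, False, False) == {
            "no_postindex_claim"
        }
        # exactly index-6 and index+12 are acceptable boundaries
        assert screen_eligibility(birth, index, {index - 6, index + 12}, False, False) == set()


FIXTURE_EXPECTATIONS = {
    "single-P1": ("P1", "2018-03"),
    "single-P2-minimal": ("P2", "2018-04"),
    "overlap-case": ("P1", "2018-03"),
    "excluded-by-ACE": (None, "ace_inhibitor"),
    "excluded-by-age": (None, "under_20"),
    "short-history": (None, "insufficient_history"),
    "no-postindex-claim": (None, "no_postindex_claim"),
}


@pytest.mark.parametrize("name", FIXTURE_NAMES)
def test_fixture_outcomes(name, books, periods):
    result = build_cohort(make_fixture(name), books, periods)
    expected_pop, detail = FIXTURE_EXPECTATIONS[name]
    if expected_pop is None:
        assert not result.assignments
        (report,) = result.exclusions.values()
        assert detail in report.reasons
    else:
        (assignment,) = result.assignments.values()
        assert assignment.population == expected_pop
        assert str(assignment.index_month) == detail


def test_unknown_fixture_name():
    with pytest.raises(ValueError, match="unknown fixture"):
        make_fixture("nope")


def test_subgroup_window_ends_at_index(books, periods):
    """A CVA code in the evaluation window plus an atopic code at index give
    both subgroups; codes after the index month do not count by default."""
    bundle = _mini_bundle(
        ym(1980, 5),
        [
            (ym(2017, 9), "Z00.0", "checkup"),
            (ym(2018, 1), "J45.9", "cough-variant asthma"),
            (ym(2018, 2), "J45.9", "cough-variant asthma"),
            (ym(2018, 4), "R05", "atopic cough"),
            (ym(2018, 5), "R05", "dry cough"),  # after index: OTHER ignored
            (ym(2018, 8), "Z00.0", "checkup"),
        ],
    )
    result = build_cohort(bundle, books, periods)
    (a,) = result.assignments.values()
    assert a.population == "P2"
    assert str(a.index_month) == "2018-04"
    assert a.subgroups == {CoughCategory.CVA, CoughCategory.ATOPIC_ALLERGIC}


def test_subgroup_full_window_option(books, periods):
    bundle = _mini_bundle(
        ym(1980, 5),
        [
            (ym(2017, 9), "Z00.0", "checkup"),
            (ym(2018, 1), "J45.9", "cough-variant asthma"),
            (ym(2018, 2), "J45.9", "cough-variant asthma"),
            (ym(2018, 4), "R05", "atopic cough"),
            (ym(2018, 5), "R05", "dry cough"),  # inside post-evaluation window
            (ym(2018, 8), "Z00.0", "checkup"),
        ],
    )
    result = build_cohort(
        bundle, books, periods, options=CohortOptions(subgroup_window="full_window")
    )
    (a,) = result.assignments.values()
    assert a.subgroups == {
        CoughCategory.CVA,
        CoughCategory.ATOPIC_ALLERGIC,
        CoughCategory.OTHER,
    }


def test_only_other_category_gives_other_subgroup(books, periods):
    result = build_cohort(make_fixture("single-P2-minimal"), books, periods)
    (a,) = result.assignments.values()
    assert CoughCategory.OTHER in a.subgroups
    assert a.subgroups  # P2 subgroups are never empty


def test_planted_bundle_recovery(noisefree_planted, books, periods):
    bundle, truth = noisefree_planted
    result = build_cohort(bundle, books, periods)
    t = truth.table.set_index("beneficiary_id")
    expected_p1 = set(t.index[t["label"] == "P1"])
    expected_p2 = set(t.index[t["label"] == "P2"])
    assert result.p1_ids == expected_p1
    assert result.p2_ids == expected_p2
    for b, a in result.assignments.items():
        assert str(a.index_month) == t.loc[b, "index_ym"]
        if a.population == "P2":
            assert "|".join(sorted(c.value for c in a.subgroups)) == t.loc[b, "subgroups"]


def test_zero_cough_rates_give_empty_cohort(books, periods):
    from coughcohort.simulate import SimulationConfig, generate

    cfg = SimulationConfig(
        n_beneficiaries=300,
        cough_category_rates={c: 0.0 for c in (
            "CHRONIC", "INFECTION", "ATOPIC_ALLERGIC", "CVA", "POSTINFECTIOUS", "OTHER"
        )},
    )
    bundle, _ = generate(cfg, seed=3)
    result = build_cohort(bundle, books, periods)
    assert not result.assignments
    assert result.flow["any_cough_code"] == 0
    assert result.flow["enrolled"] == 0
    assert result.flow["criteria_met"] == 0


def test_partition_and_p2_invariants(noisy_bundle, books, periods):
    """P1 and P2 are disjoint; every P2 member has cough codes in >=3 distinct
    months and an index at least 2 months after the first evaluation cough."""
    bundle, _ = noisy_bundle
    result = build_cohort(bundle, books, periods)
    assert result.p1_ids.isdisjoint(result.p2_ids)
    assert len(result.assignments) == len(result.p1_ids) + len(result.p2_ids)
    assert set(result.exclusions).isdisjoint(result.assignments)
    for b in result.p2_ids:
        a = result.assignments[b]
        w = a.qualifying_window
        distinct = set(w.eval_cough_months) | set(w.post_cough_months)
        assert len(distinct) >= 3
        assert a.index_month - min(w.eval_cough_months) >= 2
        assert periods.in_selection(a.index_month)
        assert a.subgroups


def test_oracle_equivalence_small(books):
    """Engine agrees with the naive all-pairs enumerator on random bundles."""
    from coughcohort.records import StudyPeriods

    trial_periods = StudyPeriods(ym(2017, 1), ym(2017, 7), ym(2018, 8), ym(2019, 8))
    rng = np.random.default_rng(2026)
    for _ in range(25):
        bundle = random_bundle(rng, 40, trial_periods)
        result = build_cohort(bundle, books, trial_periods)
        expected = oracle_assign(bundle, books, trial_periods)
        got = {
            b: (a.population, a.index_month.value, a.subgroups)
            for b, a in result.assignments.items()
        }
        assert got == expected


def test_neutral_claim_never_removes_member(noisy_bundle, books, periods):
    """Adding a non-cough, non-exclusion claim leaves every assignment intact."""
    bundle, _ = noisy_bundle
    before = build_cohort(bundle, books, periods)
    some = sorted(before.assignments)[:20]
    extra = pd.DataFrame(
        {
            "beneficiary_id": some,
            "month": [periods.selection_start.value] * len(some),
            "icd10": ["Z00.0"] * len(some),
            "standard_name": ["checkup"] * len(some),
            "facility_size": ["beds_1_19"] * len(some),
        }
    )
    bundle2 = type(bundle)(
        bundle.beneficiaries,
        pd.concat([bundle.diagnoses, extra], ignore_index=True),
        bundle.prescriptions,
    )
    after = build_cohort(bundle2, books, periods)
    assert set(before.assignments) <= set(after.assignments)
    for b in before.assignments:
        assert after.assignments[b].index_month == before.assignments[b].index_month
        assert after.assignments[b].population == before.assignments[b].population


def test_chronic_claim_at_index_moves_p2_to_p1(noisy_bundle, books, periods):
    bundle, _ = noisy_bundle
    before = build_cohort(bundle, books, periods)
    p2 = sorted(before.p2_ids)[:10]
    extra = pd.DataFrame(
        {
            "beneficiary_id": p2,
            "month": [before.assignments[b].index_month.value for b in p2],
            "icd10": ["R05"] * len(p2),
            "standard_name": ["chronic cough"] * len(p2),
            "facility_size": ["beds_1_19"] * len(p2),
        }
    )
    bundle2 = type(bundle)(
        bundle.beneficiaries,
        pd.concat([bundle.diagnoses, extra], ignore_index=True),
        bundle.prescriptions,
    )
    after = build_cohort(bundle2, books, periods)
    for b in p2:
        assert after.assignments[b].population == "P1"
        assert after.assignments[b].index_month <= before.assignments[b].index_month


def test_facility_mode_ties_break_to_larger(books, periods):
    bundle = _mini_bundle(
        ym(1980, 5),
        [
            (ym(2017, 9), "Z00.0", "checkup"),
            (ym(2018, 3), "R05", "chronic cough"),
            (ym(2018, 8), "Z00.0", "checkup"),
        ],
    )
    dx = bundle.diagnoses.copy()
    extra = pd.DataFrame(
        {
            "beneficiary_id": ["F000001"],
            "month": [ym(2018, 3).value],
            "icd10": ["J30.4"],
            "standard_name": ["allergic rhinitis"],
            "facility_size": ["beds_200_plus"],
        }
    )
    bundle2 = type(bundle)(
        bundle.beneficiaries, pd.concat([dx, extra], ignore_index=True), bundle.prescriptions
    )
    result = build_cohort(bundle2, books, periods)
    (a,) = result.assignments.values()
    assert a.facility_size == "beds_200_plus"
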