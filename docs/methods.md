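# Methods

## Phenotype model and assumptions

The pipeline operates on the coarsest unit Japanese outpatient claims offer:
the (beneficiary, calendar month) cell for diagnoses, and the calendar day for
prescriptions. All month intervals are closed on both ends, as are day
windows. A `YearMonth` is an integer count of months, so differences are
calendar-month separations and window arithmetic is exact.

**Population 1** requires one claim with the exact pair (R05, chronic cough)
inside the selection period; the index month is the earliest such month.
**Population 2** requires, among the sixteen non-chronic cough code pairs,
claims in ≥ 2 distinct months of some 3-consecutive-month evaluation window
and ≥ 1 claim in the following 3 months; the index month is the earliest
post-evaluation-window cough month and must lie in the selection period. At
monthly resolution the minimal qualifying pattern (months m, m+1, m+3) spans
well over eight weeks, which is the point of the design: the pattern is a
conservative (highly specific, imperfectly sensitive) surrogate for the
8-week duration criterion when exact visit dates are unknowable.

Candidate evaluation windows are scanned in calendar order starting at the
study start (six months before the selection period opens), and the earliest
qualifying window wins. A window may begin before the first cough month; this
makes three consecutive cough months (m, m+1, m+2) a qualifying pattern with
index m+2. The index month is invariant to which qualifying window is chosen:
any earlier qualifying start yields the same earliest post-window cough
month, and no cough months can lie between a window's start and its first
evaluation cough month, so subgroup sets are unaffected too.

Chronic-cough claims never count toward the Population-2 pattern, and any
beneficiary with a selection-period chronic-cough claim who passes screening
is assigned to Population 1, making the populations mutually exclusive by
construction. Chronic-cough claims before the selection start are ignored for
indexing (the algorithm is defined over the selection period only).

**Subgroups** of Population 2 (infection-associated, atopic/allergic,
cough-variant asthma, post-infectious, other) are the categories of all
non-chronic cough claims from the qualifying window start through the index
month inclusive. A config switch (`CohortOptions.subgroup_window =
"full_window"`) instead uses the whole evaluation plus post-evaluation window
regardless of the index month; the two conventions differ only for cough
claims between the index month and the end of the post-evaluation window.
The default ends at the index month.

**Eligibility screens.** Age at index is the floor of (index − birth
month)/12 — only year/month of birth exists, so completed years are a lower
bound. Database membership spells are not recorded, so "documented for six
months before index" is proxied by first-ever claim month ≤ index − 6
(diagnosis or prescription). The ACE-inhibitor (ATC prefix C9A/C9B) and
organic-respiratory/cancer screens apply to claims anywhere in the study
period. The post-index continuity screen requires any claim in
[index+1, index+12].

**Facility size at index** is the mode of the facility-size field over the
member's index-month diagnosis claims, ties broken toward the larger
category; members with no sized claim are "unknown" and drop out of the
facility denominator.

## Extraction conventions

Counting is participant-level everywhere: one member counts once per
category/disease/class per window. Disease windows are [index, index],
[index−6, index] (pre-index, including the index month) and
[index+10, index+12]. The months-10–12 denominator is the *evaluable* subset:
members with ≥ 1 cough-coded or cough-related-disease-coded diagnosis claim
in that window (prescriptions do not confer evaluability).

Drug-utilisation windows: the index-month window is the whole index calendar
month, because the index day is unknown while prescriptions "for the index
month" are month-scoped. At post-index month k ∈ {1, 2, 3, 6, 9, 12} the
window is ±14 days around an anchor on the 15th of calendar month index+k —
the anchor day is a declared approximation (the source data record no index
day), chosen to centre the four-week window on the month; it implies days
1–29 of that month are covered. The window denominator is the number of
members with ≥ 1 prescription of any of the ten classes of interest inside
the window (ACE inhibitors are excluded upstream and are never a class of
interest). "Central antitussives alone" are members whose window contains
only that class. A member counts under "other bronchodilators" only when no
ICS/LABA combination falls in the same window; the antitussive
co-prescription flag is a property of the window, shared by every class in
it, so `with + without = total` holds identically per class.

**Persistence partition** at months 10–12 classifies each enrolled member by
priority: original category code present → retained; else any other cough
category code → moved to another cough code; else (evaluable, so a disease
code must be present) → disease code only; non-evaluable → left the cohort.
The published category counts are non-exclusive; both the non-exclusive table
view and the exclusive partition are produced and labelled distinctly.

**Rounding** is half-up to one decimal via exact decimal arithmetic, which
reproduces every recomputable published percentage. A zero denominator yields
an explicit undefined marker, never a division error. Table rows flag a
disease whose proportion changes by more than 5 percentage points between the
pre-index period and months 10–12.

## Synthetic generator

The generator emulates the structural features the algorithm depends on:
month-stamped diagnoses carrying (ICD-10, standard name) pairs (including the
R05 subtype disambiguation), day-stamped ATC prescriptions placed on uniform
random days of consult months so the ±14-day logic is exercised, demographic
mix (default mean age 43.7 ± 12.2 years, 61.8% women, truncated to the
under-75 insured profile), facility-size mix (0.699/0.087/0.214), and
enrolment attrition. Attrition is geometric per month with survival
calibrated to the annual figure: monthly leaving probability
1 − (1 − a)^(1/12), default a = 0.14/year; by memorylessness the conditional
probability of leaving within any 12-month window is exactly a. Entry churn
is not modelled (all beneficiaries are present from the study start), nor are
physician coding behaviour, seasonal epidemics, or dose/duration — so passing
tests demonstrate algorithmic correctness on structurally faithful data, not
clinical realism of any rate.

Per-consultation cough-category rates, per-beneficiary disease prevalences
and conditional medication probabilities are configurable; defaults are set
once to loosely echo the observed index-month mix (e.g. other-cough and
cough-variant-asthma codes dominate Population 2, expectorants are the most
common cough prescription). Planted Population-1 members carry a chronic
cough claim at a random selection month plus history and post-index anchor
claims; planted Population-2 members carry cough claims at two distinct
months of an evaluation window and an index in the post-window, never emit a
random chronic-cough claim, and are never flagged for ACE/exclusion
diagnoses, so their intended label, index month and subgroup set are exact
ground truth under noise-free rates. The minimal-pattern index month is
provably invariant to background-free window choice, so recovery is exact
rather than approximate.

## Validation design and problem sizes

* Brute-force oracle: an independent all-pairs enumerator of (window start,
  index) candidates plus straight-line screening, compared with the engine on
  500 random adversarial bundles of up to ~45 beneficiaries over a 32-month
  study span.
* Planted recovery: 1,000 beneficiaries (100 planted Population 1, 50
  Population 2, zero background cough rates); sensitivity and specificity
  must both be exactly 1.
* Attrition calibration: 20,000 beneficiaries; the conditional 12-month
  dropout among those enrolled at month 12 must sit within three binomial
  standard errors of the configured rate. (The *cumulative* fraction dropped
  over the whole observation span is necessarily larger than the annual rate
  and is not the calibrated quantity.)
* Published-arithmetic reconciliation: the persistence columns and flow
  counts of the published tables are encoded as minimal synthetic claim
  patterns; running the full cohort → evaluability → partition chain must
  reproduce the printed derived figures (470/104/710 of 1,284; 427/25/163 of
  615; 12,467 − 6,429 = 6,038) and their half-up percentages exactly.

These sizes keep the whole suite under a few tens of seconds on one CPU while
leaving the statistical checks well-powered.

## Known limitations

* The bundled disease and medication codebooks are synthetic stand-ins; real
  analyses must supply the licensed code lists.
* One spec-level invariant ("adding any non-exclusion claim never removes a
  member") is not true of the phenotype itself: a new cough claim can shift
  the index month earlier and break the history or follow-up screen. The
  package implements the definitions faithfully and asserts the restricted
  monotonicity properties that do hold.
* The flow step "adults with a selection-period claim" evaluates age at the
  selection end (individual cohort ages are evaluated at index); flow counts
  are descriptive, not an eligibility surface.
* Standard disease names are matched as exact opaque strings; no fuzzy or
  vernacular matching is attempted.
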