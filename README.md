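# coughcohort

A tested, reusable pipeline for identifying and describing chronic-cough
patients in Japanese-style administrative claims data, where outpatient
diagnoses are recorded at **month** resolution and prescriptions at **day**
resolution. It is aimed at pharmacoepidemiologists building computable
phenotypes over claims tables: the package implements the cohort algorithm,
window extraction and table assembly as a library with a thin CLI, and ships a
synthetic claims generator so every step can be validated against planted
ground truth.

## The phenotype

Chronic cough is a cough lasting more than 8 weeks. There is no single ICD-10
code for it, so two mutually exclusive populations are identified over a
selection period:

* **Population 1** — at least one claim carrying the ICD-10 code R05 together
  with the standard disease name for chronic cough (Japanese claims attach a
  vernacular "standard disease name" that disambiguates the many cough
  subtypes sharing R05). Index month = first such month.
* **Population 2** — no chronic-cough claim, but other diagnostic cough codes
  (infection-associated, atopic/allergic, cough-variant asthma,
  post-infectious, other coughs) in ≥ 2 distinct months of a 3-consecutive-
  month *evaluation window*, followed by ≥ 1 further cough code in the next
  3-month *post-evaluation window*. Index month = earliest post-window cough
  month. At monthly resolution this pattern guarantees > 8 weeks of cough.

Anyone meeting both definitions goes to Population 1. Eligibility screening
then removes members aged < 20 at index, any ACE-inhibitor user (ATC C9A/C9B,
a classic iatrogenic cough cause), organic respiratory disease or cancer,
insufficient pre-index history (first-ever claim later than index − 6 months)
and members with no claim in the 12 post-index months.

Around each member's index month the pipeline extracts, with participant-level
counting and the study's denominators:

* cough categories at index and months 10–12 (denominator: members still
  *evaluable* there, i.e. with a cough or cough-related-disease claim);
* ten cough-related diseases (allergic rhinitis/nasal inflammation, asthma,
  GERD, …) at index, over the pre-index period `[index−6, index]`, and at
  months 10–12;
* medication classes (central antitussives, expectorants, antiallergics,
  restricted antimicrobials, ICS/LABA, …) in the index calendar month and in
  ±14-day windows around the 15th of months index+1, 2, 3, 6, 9, 12 —
  each class split by central-antitussive co-prescription;
* the diagnosis-persistence partition at months 10–12: retained original
  code / other cough code / disease code only / left the cohort.

All percentages are rounded half-up to one decimal; the analysis is purely
descriptive.

## Worked example

```python
import coughcohort as cc

cfg = cc.SimulationConfig(n_beneficiaries=2000, planted_p1=80, planted_p2=60)
bundle, truth = cc.generate(cfg, seed=1)
books, periods = cc.default_codebooks(), cc.StudyPeriods()

cohort = cc.build_cohort(bundle, books, periods)
print(cohort.flow)

summaries = cc.extract_summaries(cohort, bundle, books, periods)
tables = cc.build_tables(summaries)
for row in tables["T6"].rows[:3]:
    print(row)
```

prints

```
{'any_claim': 1658, 'adults_with_selection_claim': 1502, 'any_cough_code': 423,
 'criteria_met': 238, 'excluded_eligibility': 46, 'enrolled': 192}
{'population': 'All', 'label': 'any_medication', 'count': 68, 'denominator': 192, 'percent': '35.4%'}
{'population': 'All', 'label': 'central_antitussives_only', 'count': 1, 'denominator': 68, 'percent': '1.5%'}
{'population': 'All', 'label': 'expectorant:all', 'count': 28, 'denominator': 68, 'percent': '41.2%'}
```

Of 2,000 simulated beneficiaries, 1,658 make a claim, 423 adults carry a cough
code in the selection period, 238 meet the temporal cough criteria and 192
survive eligibility screening (134 Population 1, 58 Population 2 — every
planted member among them). At the index month 68 cohort members receive a
medication of interest (35.4% of the cohort — the simulation's consult and
prescribing rates are thinner than real claims); one receives a central
antitussive alone, and 41.2% of medication users receive an expectorant.

The same pipeline runs from the shell:

```
coughcohort simulate --seed 1 --out-dir claims/
coughcohort build-cohort --claims-dir claims/ --out-dir cohort/
coughcohort extract --claims-dir claims/ --cohort-dir cohort/ --out summaries.json
coughcohort report --summaries summaries.json --out-dir tables/
# or all stages with one config + reproducibility manifest:
coughcohort run --config run.yaml
```

Claims live in three UTF-8 tab-delimited tables (`beneficiaries.tsv`,
`diagnoses.tsv`, `prescriptions.tsv`; months as `YYYY-MM`, days ISO); the
three codebooks (cough pairs, disease prefixes, ATC prefixes) are a single
YAML file. The bundled cough codebook is the seventeen-pair population
definition; the bundled disease/medication codebooks are synthetic stand-ins
on plausible ICD-10 chapters and ATC-style leaves — supply your own for real
analyses.

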