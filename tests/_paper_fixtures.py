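"""Claims-level fixtures encoding published summary counts (synthetic).

These bundles are synthetic reconstructions: each beneficiary is given the
minimal claim pattern that reproduces one column of the published persistence
tables, so the pipeline's cohort, evaluability and partition operations can be
checked against the printed derived figures.  Counts are inputs here, not
outputs of any real data.
"""

from __future__ import annotations

import pandas as pd

from coughcohort.months import ym
from coughcohort.records import ClaimsBundle, empty_prescriptions

_CHRONIC = ("R05", "chronic cough")
_OTHER = ("R05", "dry cough")
_CVA = ("J45.9", "cough-variant asthma")
_ATOPIC = ("R05", "atopic cough")
_INFECTION = ("A37.9", "whooping cough")
_POSTINF = ("R05", "post-infectious cough")
_ARNI = ("J30.4", "allergic rhinitis")
_NEUTRAL = ("Z00.0", "general examination")

#: Months 10-12 outcome mix of the published Population-1 column:
#: (claim pair at index+11 or None, member count).  1,284 evaluable members
#: partition 470 retained / 104 other cough / 710 disease-only; the other
#: 2,216 of the 3,500 enrolled leave the cohort.
P1_M10_12_MIX = (
    (_CHRONIC, 470),
    (_OTHER, 46),
    (_CVA, 36),
    (_ATOPIC, 7),
    (_INFECTION, 9),
    (_POSTINF, 6),
    (_ARNI, 710),
    (None, 2216),
)

#: Cough-variant-asthma subgroup column: 615 evaluable of 1,026 enrolled,
#: partitioned 427 retained / 25 other cough / 163 disease-only.
CVA_M10_12_MIX = (
    (_CVA, 427),
    (_OTHER, 25),
    (_ARNI, 163),
    (None, 411),
)


def _bundle(rows_per_member, prefix: str) -> ClaimsBundle:
    ids, dx = [], []
    for i, rows in enumerate(rows_per_member):
        b = f"{prefix}{i:05d}"
        ids.append(b)
        for month, (icd, name) in rows:
            dx.append((b, month.value, icd, name))
    beneficiaries = pd.DataFrame(
        {"id": ids, "birth_m": [ym(1978, 6).value] * len(ids), "gender": ["female"] * len(ids)}
    )
    diagnoses = pd.DataFrame(dx, columns=["beneficiary_id", "month", "icd10", "standard_name"])
    diagnoses["facility_size"] = "beds_1_19"
    return ClaimsBundle(beneficiaries, diagnoses, empty_prescriptions()).validate()


def p1_persistence_bundle() -> ClaimsBundle:
    """3,500 Population-1 members, index 2018-01, months 10-12 per the mix."""
    index = ym(2018, 1)
    members = []
    for pair, count in P1_M10_12_MIX:
        for _ in range(count):
            rows = [
                (index - 6, _NEUTRAL),  # six months of history
                (index, _CHRONIC),
                (index + 2, _NEUTRAL),  # keeps the post-index screen satisfied
            ]
            if pair is not None:
                rows.append((index + 11, pair))
            members.append(rows)
    return _bundle(members, "P")


def cva_persistence_bundle() -> ClaimsBundle:
    """1,026 Population-2 cough-variant-asthma members, index 2018-04."""
    index = ym(2018, 4)
    members = []
    for pair, count in CVA_M10_12_MIX:
        for _ in range(count):
            rows = [
                (ym(2017, 9), _NEUTRAL),
                (ym(2018, 1), _CVA),
                (ym(2018, 2), _CVA),
                (index, _CVA),
                (index + 2, _NEUTRAL),
            ]
            if pair is not None:
                rows.append((index + 11, pair))
            members.append(rows)
    return _bundle(members, "V")
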