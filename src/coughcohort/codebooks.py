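"""Codebooks mapping claim codes to analysis categories.

Three lookup structures drive the pipeline:

* ``CoughCodebook`` — exact ``(ICD-10 code, standard disease name)`` pairs to a
  cough category.  Japanese claims attach a vernacular "standard disease name"
  to each ICD-10 code, which disambiguates the many cough subtypes that share
  the single code R05; matching is therefore exact-string on the pair.  The
  bundled default holds the seventeen pairs used to define the two study
  populations: the single chronic-cough entry defines Population 1, the other
  sixteen define Population 2.
* ``DiseaseCodebook`` — ICD-10 code (longest-prefix match) to one of ten
  cough-related disease labels or to an exclusion label (organic respiratory
  disease, cancer).
* ``MedicationCodebook`` — ATC class code (longest-prefix match) to one of
  eleven medication classes; any code starting C9A or C9B is an ACE inhibitor
  and an exclusion criterion.

The bundled disease and medication codebooks are synthetic stand-ins built on
plausible ICD-10 chapters and ATC-style leaves; real analyses supply their own
via :func:`load_codebooks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml


class CoughCategory(str, Enum):
    CHRONIC = "CHRONIC"
    INFECTION = "INFECTION"
    ATOPIC_ALLERGIC = "ATOPIC_ALLERGIC"
    CVA = "CVA"
    POSTINFECTIOUS = "POSTINFECTIOUS"
    OTHER = "OTHER"


#: Categories whose codes define Population 2 (everything except CHRONIC).
POP2_CATEGORIES = frozenset(
    {
        CoughCategory.INFECTION,
        CoughCategory.ATOPIC_ALLERGIC,
        CoughCategory.CVA,
        CoughCategory.POSTINFECTIOUS,
        CoughCategory.OTHER,
    }
)


class DiseaseLabel(str, Enum):
    ARNI = "ARNI"  # allergic rhinitis / nasal inflammation
    ASTHMA = "asthma"
    GERD = "GERD"
    PARANASAL_SINUSITIS = "paranasal_sinusitis"
    CAID = "CAID"  # chronic airway inflammatory disease
    CHRONIC_RHINITIS = "chronic_rhinitis"
    POSTNASAL_DRIP = "postnasal_drip"
    VOCAL_CORD_DYSFUNCTION = "vocal_cord_dysfunction"
    EMPHYSEMA = "emphysema"
    NASAL_POLYPS = "nasal_polyps"
    EXCL_ORGANIC_RESPIRATORY = "EXCL_organic_respiratory"
    EXCL_CANCER = "EXCL_cancer"


#: The ten cough-related diseases tracked per window (exclusion labels aside).
COUGH_RELATED_DISEASES = tuple(
    d for d in DiseaseLabel if not d.value.startswith("EXCL_")
)

EXCLUSION_LABELS = (DiseaseLabel.EXCL_ORGANIC_RESPIRATORY, DiseaseLabel.EXCL_CANCER)


class MedicationClass(str, Enum):
    CENTRAL_ANTITUSSIVE = "central_antitussive"
    EXPECTORANT = "expectorant"
    ANTIALLERGIC = "antiallergic"
    # Respiratory quinolones and 14- and 15-member ring macrolides only.
    ANTIMICROBIAL_RESTRICTED = "antimicrobial_restricted"
    ICS_LABA = "ICS_LABA"
    HERBAL = "herbal"
    CORTICOSTEROID = "corticosteroid"
    BRONCHODILATOR_OTHER = "bronchodilator_other"
    PEPTIC_ULCER = "peptic_ulcer"
    GI_MOTILITY = "GI_motility"
    ACE_INHIBITOR = "ACE_inhibitor"


#: Medication classes of interest for drug-utilisation windows: everything
#: except ACE inhibitors, whose users are excluded from the cohort upstream.
CLASSES_OF_INTEREST = tuple(
    c for c in MedicationClass if c is not MedicationClass.ACE_INHIBITOR
)


class CodebookError(ValueError):
    """Raised for duplicate entries or unknown category labels."""


@dataclass(frozen=True)
class CoughCodebook:
    """Exact (icd10, standard_name) -> cough category lookup."""

    entries: dict[tuple[str, str], CoughCategory]

    def category(self, icd10: str, standard_name: str) -> CoughCategory | None:
        return self.entries.get((icd10, standard_name))

    @classmethod
    def from_rows(cls, rows) -> "CoughCodebook":
        entries: dict[tuple[str, str], CoughCategory] = {}
        for icd10, name, cat in rows:
            key = (icd10, name)
            if key in entries:
                raise CodebookError(f"duplicate cough codebook pair: {key}")
            try:
                entries[key] = CoughCategory(cat)
            except ValueError:
                raise CodebookError(f"unknown cough category: {cat!r}") from None
        return cls(entries)


class _PrefixCodebook:
    """Longest-prefix lookup from a code string to a label."""

    def __init__(self, entries: dict[str, Enum]):
        self.entries = dict(entries)
        self._by_len = sorted(self.entries, key=len, reverse=True)

    def label(self, code: str):
        for prefix in self._by_len:
            if code.startswith(prefix):
                return self.entries[prefix]
        return None


class DiseaseCodebook(_PrefixCodebook):
    """ICD-10 prefix -> cough-related disease or exclusion label."""

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "DiseaseCodebook":
        entries: dict[str, DiseaseLabel] = {}
        for code, label in mapping.items():
            if code in entries:
                raise CodebookError(f"duplicate disease code: {code}")
            try:
                entries[code] = DiseaseLabel(label)
            except ValueError:
                raise CodebookError(f"unknown disease label: {label!r}") from None
        return cls(entries)


class MedicationCodebook(_PrefixCodebook):
    """ATC prefix -> medication class; C9A/C9B always map to ACE inhibitors."""

    def __init__(self, entries: dict[str, MedicationClass]):
        entries = dict(entries)
        entries.setdefault("C9A", MedicationClass.ACE_INHIBITOR)
        entries.setdefault("C9B", MedicationClass.ACE_INHIBITOR)
        for prefix in ("C9A", "C9B"):
            if entries[prefix] is not MedicationClass.ACE_INHIBITOR:
                raise CodebookError(f"{prefix} must map to ACE_inhibitor")
        super().__init__(entries)

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "MedicationCodebook":
        entries: dict[str, MedicationClass] = {}
        for code, label in mapping.items():
            if code in entries:
                raise CodebookError(f"duplicate ATC code: {code}")
            try:
                entries[code] = MedicationClass(label)
            except ValueError:
                raise CodebookError(f"unknown medication class: {label!r}") from None
        return cls(entries)


# --- bundled defaults -------------------------------------------------------

# The diagnostic cough codes and standard disease names defining the two
# study populations.  Standard names are romanised opaque keys.
DEFAULT_COUGH_ROWS: tuple[tuple[str, str, str], ...] = (
    # Population 1 — the single chronic-cough entry
    ("R05", "chronic cough", "CHRONIC"),
    # Population 2 — cough associated with infection
    ("A16.9", "tuberculous cough", "INFECTION"),
    ("A37.0", "whooping cough (B. pertussis)", "INFECTION"),
    ("A37.9", "whooping cough", "INFECTION"),
    # atopic / allergic cough
    ("R05", "atopic cough", "ATOPIC_ALLERGIC"),
    ("R05", "allergic cough", "ATOPIC_ALLERGIC"),
    # cough-variant asthma
    ("J45.9", "cough-variant asthma", "CVA"),
    # post-infectious cough
    ("R05", "post-infectious cough", "POSTINFECTIOUS"),
    # other coughs
    ("F45.3", "psychogenic cough", "OTHER"),
    ("G44.8", "primary cough headache", "OTHER"),
    ("R05", "catarrhal cough", "OTHER"),
    ("R05", "cough", "OTHER"),
    ("R05", "syncope cough", "OTHER"),
    ("R05", "dry cough", "OTHER"),
    ("R05", "wet cough", "OTHER"),
    ("R05", "prolonged subacute cough", "OTHER"),
    ("R05", "nocturnal cough", "OTHER"),
)

# Synthetic stand-in disease map on plausible ICD-10 chapters.
DEFAULT_DISEASE_MAP: dict[str, str] = {
    "J30": "ARNI",
    "J45": "asthma",
    "K21": "GERD",
    "J32": "paranasal_sinusitis",
    "J44": "CAID",
    "J31": "chronic_rhinitis",
    "R09.8": "postnasal_drip",
    "J38.3": "vocal_cord_dysfunction",
    "J43": "emphysema",
    "J33": "nasal_polyps",
    "J84": "EXCL_organic_respiratory",
    "E84": "EXCL_organic_respiratory",
    "J47": "EXCL_organic_respiratory",
    "C": "EXCL_cancer",
}

# Synthetic stand-in medication map on ATC-style leaves.
DEFAULT_MEDICATION_MAP: dict[str, str] = {
    "R05D": "central_antitussive",
    "R05C": "expectorant",
    "R06A": "antiallergic",
    "J01FA": "antimicrobial_restricted",  # 14/15-membered macrolides
    "J01MA": "antimicrobial_restricted",  # respiratory quinolones
    "R03AK": "ICS_LABA",
    "V90": "herbal",
    "H02AB": "corticosteroid",
    "R03AC": "bronchodilator_other",
    "R03BB": "bronchodilator_other",
    "R03DA": "bronchodilator_other",
    "A02BC": "peptic_ulcer",
    "A02BA": "peptic_ulcer",
    "A03FA": "GI_motility",
    "C9A": "ACE_inhibitor",
    "C9B": "ACE_inhibitor",
}


@dataclass
class Codebooks:
    cough: CoughCodebook
    disease: DiseaseCodebook
    medication: MedicationCodebook


def default_codebooks() -> Codebooks:
    return Codebooks(
        cough=CoughCodebook.from_rows(DEFAULT_COUGH_ROWS),
        disease=DiseaseCodebook.from_mapping(DEFAULT_DISEASE_MAP),
        medication=MedicationCodebook.from_mapping(DEFAULT_MEDICATION_MAP),
    )


def load_codebooks(path: str | Path) -> Codebooks:
    """Load the three codebooks from one YAML file.

    Layout::

        cough:
          - [icd10, standard_name, category]
        diseases:
          icd10_prefix: label
        medications:
          atc_prefix: class
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CodebookError(f"codebook file {path} is not a mapping")
    for key in ("cough", "diseases", "medications"):
        if key not in raw:
            raise CodebookError(f"codebook file missing section {key!r}")
    cough_rows = []
    seen: set[tuple[str, str]] = set()
    for row in raw["cough"]:
        if not isinstance(row, (list, tuple)) or len(row) != 3:
            raise CodebookError(f"cough entry must be [icd10, name, category]: {row!r}")
        key = (str(row[0]), str(row[1]))
        if key in seen:
            raise CodebookError(f"duplicate cough codebook pair: {key}")
        seen.add(key)
        cough_rows.append((str(row[0]), str(row[1]), str(row[2])))
    return Codebooks(
        cough=CoughCodebook.from_rows(cough_rows),
        disease=DiseaseCodebook.from_mapping(
            {str(k): str(v) for k, v in raw["diseases"].items()}
        ),
        medication=MedicationCodebook.from_mapping(
            {str(k): str(v) for k, v in raw["medications"].items()}
        ),
    )


def dump_codebooks(books: Codebooks, path: str | Path) -> None:
    """Write codebooks in the :func:`load_codebooks` YAML layout."""
    payload = {
        "cough": [
            [icd, name, cat.value] for (icd, name), cat in books.cough.entries.items()
        ],
        "diseases": {k: v.value for k, v in books.disease.entries.items()},
        "medications": {k: v.value for k, v in books.medication.entries.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)
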