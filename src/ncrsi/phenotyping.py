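"""Rule-based phenotyping of free-text diagnosis and medication fields.

Text is normalized (lowercased, diacritics stripped, whitespace collapsed)
and matched against keyword dictionaries by plain substring search. EMR
diagnosis fields are semi-structured term lists, so substring matching with
curated (often stemmed) multi-word terms is the intended behaviour; negation
and temporality are deliberately not handled and remain a documented
misclassification source.

The bundled dictionaries mix English and Romanian clinical vocabulary and
are stand-ins: real deployments should supply site-specific term lists via
the same YAML format.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .cohort import PatientRecord

__all__ = [
    "NEURO_CATEGORIES",
    "CARDIOMETABOLIC_CATEGORIES",
    "CHARLSON_TEXT_CATEGORIES",
    "PSYCHOTROPIC_CLASSES",
    "KNOWN_CATEGORIES",
    "KeywordDictionary",
    "PhenotypeFlags",
    "ConfigError",
    "normalize_text",
    "load_dictionaries",
    "default_dictionaries",
    "extract_flags",
]


class ConfigError(ValueError):
    """Invalid dictionary or configuration file."""


#: neuro-psychic burden categories detected in diagnosis text
NEURO_CATEGORIES = frozenset(
    {"anxiety", "depressive", "sleep", "psychosomatic", "cognitive", "severe_psychiatric"}
)
#: cardiometabolic diagnoses detected in diagnosis text
CARDIOMETABOLIC_CATEGORIES = frozenset(
    {"hypertension", "diabetes", "dyslipidemia", "obesity_metsyn"}
)
#: Charlson categories detectable from diagnosis text
CHARLSON_TEXT_CATEGORIES = frozenset(
    {"chf", "cerebrovascular", "dementia", "pulmonary", "diabetes", "malignancy"}
)
#: psychotropic medication classes detected in the medication field
PSYCHOTROPIC_CLASSES = frozenset({"anxiolytic", "antidepressant", "antipsychotic"})

KNOWN_CATEGORIES = frozenset(
    NEURO_CATEGORIES
    | CARDIOMETABOLIC_CATEGORIES
    | CHARLSON_TEXT_CATEGORIES
    | PSYCHOTROPIC_CLASSES
    | {"dialysis"}
)

_WHITESPACE = re.compile(r"\s+")


def normalize_text(raw: str | None) -> str:
    """Lowercase, strip diacritics, collapse whitespace.

    Idempotent; the empty string maps to itself.
    """
    if raw is None:
        return ""
    decomposed = unicodedata.normalize("NFKD", str(raw))
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return _WHITESPACE.sub(" ", stripped.lower()).strip()


@dataclass(frozen=True)
class KeywordDictionary:
    """One category and its (already-normalized) search terms."""

    category: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in KNOWN_CATEGORIES:
            raise ConfigError(f"unknown phenotype category {self.category!r}")
        if not self.terms:
            raise ConfigError(f"category {self.category!r} has no terms")
        for term in self.terms:
            if not term or term != normalize_text(term):
                raise ConfigError(
                    f"category {self.category!r}: term {term!r} is empty or not normalized"
                )

    def matches(self, normalized_text: str) -> bool:
        return any(term in normalized_text for term in self.terms)


@dataclass(frozen=True)
class PhenotypeFlags:
    """Per-patient boolean indicator sets extracted from free text."""

    patient_id: str
    neuro_categories: frozenset[str] = frozenset()
    psychotropic_classes: frozenset[str] = frozenset()
    cardiometabolic_dx: frozenset[str] = frozenset()
    charlson_categories: frozenset[str] = frozenset()
    dialysis_documented: bool = False


def load_dictionaries(path: str | Path) -> list[KeywordDictionary]:
    """Load keyword dictionaries from a YAML mapping of category -> term list."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("dictionary file must be a mapping of category -> term list")
    dictionaries = []
    for category, terms in raw.items():
        if not isinstance(terms, list):
            raise ConfigError(f"category {category!r}: terms must be a list")
        dictionaries.append(
            KeywordDictionary(category=category, terms=tuple(normalize_text(t) for t in terms))
        )
    return dictionaries


def default_dictionaries() -> list[KeywordDictionary]:
    """The bundled English/Romanian dictionaries (stand-in term lists)."""
    source = resources.files("ncrsi.data").joinpath("default_dictionaries.yml")
    with resources.as_file(source) as path:
        return load_dictionaries(path)


def extract_flags(
    record: PatientRecord, dictionaries: Sequence[KeywordDictionary]
) -> PhenotypeFlags:
    """Extract per-patient indicator sets by substring matching.

    Diagnosis categories are matched against the normalized diagnosis text;
    medication classes against the normalized medication text; dialysis
    against either text or the structured dialysis flag. Deterministic for
    fixed inputs, and monotone: adding a term to a dictionary can only add
    flags, never remove one.
    """
    dx_text = normalize_text(record.diagnosis_text)
    med_text = normalize_text(record.medication_text)

    neuro: set[str] = set()
    psychotropic: set[str] = set()
    cardio: set[str] = set()
    charlson: set[str] = set()
    dialysis = bool(record.dialysis_flag)

    for dictionary in dictionaries:
        cat = dictionary.category
        if cat in PSYCHOTROPIC_CLASSES:
            if dictionary.matches(med_text):
                psychotropic.add(cat)
        elif cat == "dialysis":
            if dictionary.matches(dx_text) or dictionary.matches(med_text):
                dialysis = True
        else:
            if dictionary.matches(dx_text):
                if cat in NEURO_CATEGORIES:
                    neuro.add(cat)
                if cat in CARDIOMETABOLIC_CATEGORIES:
                    cardio.add(cat)
                if cat in CHARLSON_TEXT_CATEGORIES:
                    charlson.add(cat)

    return PhenotypeFlags(
        patient_id=record.patient_id,
        neuro_categories=frozenset(neuro),
        psychotropic_classes=frozenset(psychotropic),
        cardiometabolic_dx=frozenset(cardio),
        charlson_categories=frozenset(charlson),
        dialysis_documented=dialysis,
    )


def flags_frame(all_flags: Iterable[PhenotypeFlags]):
    """Tabulate flags for audit output (one row per patient)."""
    import pandas as pd

    rows = []
    for f in all_flags:
        rows.append(
            {
                "patient_id": f.patient_id,
                "neuro_categories": ";".join(sorted(f.neuro_categories)),
                "psychotropic_classes": ";".join(sorted(f.psychotropic_classes)),
                "cardiometabolic_dx": ";".join(sorted(f.cardiometabolic_dx)),
                "charlson_categories": ";".join(sorted(f.charlson_categories)),
                "dialysis_documented": f.dialysis_documented,
            }
        )
    return pd.DataFrame(rows)
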