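"""Domain scoring and the composite Neuro-Cardio-Renal Stress Index.

The index sums three integer domain scores:

* neuro-psychic (N): accumulation of documented indicators — distinct
  text-derived symptom categories and psychotropic medication use — not
  symptom severity;
* cardiometabolic (C): TyG band points plus one point for any documented
  cardiometabolic diagnosis;
* renal (R): points by CKD stage, with dialysis forcing the maximum.

Under the original weighting N and C range 0-3 and R ranges 0-4 (total
0-10). Two symmetric alternatives are provided for sensitivity analysis:
``symmetric_3`` (0-3 per domain, total 0-9; collapses G4 with G5/dialysis)
and ``symmetric_4`` (0-4 per domain, total 0-12; adds a fourth accumulation
rule for N and a TyG >= 9.5 band for C).

TyG cut-offs (default 8.5 / 9.0, plus 9.5 in the expanded scheme) sit near
widely used insulin-resistance bands and are configuration, not data-driven
fits; the threshold-sensitivity runner perturbs them by +/-0.2.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .biomarkers import BiomarkerPanel, biomarker_panel
from .cohort import PatientRecord
from .phenotyping import (
    KeywordDictionary,
    PhenotypeFlags,
    default_dictionaries,
    extract_flags,
)

__all__ = [
    "WeightingScheme",
    "DomainScores",
    "ORIGINAL",
    "SYMMETRIC_3",
    "SYMMETRIC_4",
    "SCHEMES",
    "score_neuro",
    "score_cardiometabolic",
    "score_renal",
    "total_score",
    "categorize",
    "classify_group",
    "score_record",
    "score_cohort",
]

CATEGORIES = ("low", "moderate", "high")
GROUPS = ("cardiometabolic", "renometabolic", "other")

#: eGFR below this (mL/min/1.73 m^2) counts as reduced renal function
REDUCED_RENAL_EGFR = 60.0


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class WeightingScheme:
    """Per-domain maxima plus the mapping rules that realize them."""

    name: str
    n_max: int
    c_max: int
    r_max: int
    renal_stage_points: Mapping[str, int]
    dialysis_points: int
    tyg_thresholds: tuple[float, ...]
    #: category-count thresholds, each satisfied threshold is worth 1 N point
    neuro_count_rules: tuple[int, ...]
    #: whether >=1 psychotropic class contributes 1 N point
    psychotropic_rule: bool = True

    def __post_init__(self) -> None:
        if list(self.tyg_thresholds) != sorted(self.tyg_thresholds):
            raise ValueError("tyg_thresholds must be ascending")
        points = [self.renal_stage_points[s] for s in ("G1", "G2", "G3a", "G3b", "G4", "G5")]
        if points != sorted(points):
            raise ValueError("renal stage points must be nondecreasing with severity")

    @property
    def max_points(self) -> tuple[int, int, int]:
        return (self.n_max, self.c_max, self.r_max)

    @property
    def total_max(self) -> int:
        return self.n_max + self.c_max + self.r_max

    def with_tyg_shift(self, delta: float) -> "WeightingScheme":
        """Scheme variant with all TyG cut-offs shifted by ``delta``."""
        if abs(delta) > 0.5:
            raise ValueError("TyG threshold shift must have magnitude <= 0.5")
        return replace(
            self,
            name=f"{self.name}{delta:+.2f}" if delta else self.name,
            tyg_thresholds=tuple(t + delta for t in self.tyg_thresholds),
        )

    def category_bounds(self) -> tuple[int, int]:
        """(upper bound of low, upper bound of moderate), inclusive.

        The original 0-10 scale uses 3 and 6; other scales rescale the
        boundaries proportionally with round-half-up.
        """
        scale = self.total_max / 10.0
        return (_round_half_up(3 * scale), _round_half_up(6 * scale))


_ORIGINAL_RENAL = {"G1": 0, "G2": 0, "G3a": 1, "G3b": 2, "G4": 3, "G5": 4}

ORIGINAL = WeightingScheme(
    name="original",
    n_max=3,
    c_max=3,
    r_max=4,
    renal_stage_points=_ORIGINAL_RENAL,
    dialysis_points=4,
    tyg_thresholds=(8.5, 9.0),
    neuro_count_rules=(1, 2),
)

SYMMETRIC_3 = WeightingScheme(
    name="symmetric_3",
    n_max=3,
    c_max=3,
    r_max=3,
    renal_stage_points={"G1": 0, "G2": 0, "G3a": 1, "G3b": 2, "G4": 3, "G5": 3},
    dialysis_points=3,
    tyg_thresholds=(8.5, 9.0),
    neuro_count_rules=(1, 2),
)

SYMMETRIC_4 = WeightingScheme(
    name="symmetric_4",
    n_max=4,
    c_max=4,
    r_max=4,
    renal_stage_points=_ORIGINAL_RENAL,
    dialysis_points=4,
    tyg_thresholds=(8.5, 9.0, 9.5),
    neuro_count_rules=(1, 2, 3),
)

SCHEMES: dict[str, WeightingScheme] = {
    s.name: s for s in (ORIGINAL, SYMMETRIC_3, SYMMETRIC_4)
}


@dataclass(frozen=True)
class DomainScores:
    """The three domain scores, composite total and derived labels."""

    patient_id: str
    n_points: int
    c_points: int
    r_points: int
    total: int
    scheme: str
    category: str
    group: str

    def __post_init__(self) -> None:
        if self.total != self.n_points + self.c_points + self.r_points:
            raise ValueError("total must equal the sum of domain points")


def score_neuro(flags: PhenotypeFlags, scheme: WeightingScheme = ORIGINAL) -> int:
    """Neuro-psychic points: one per satisfied accumulation rule, capped.

    Rules: reaching each category-count threshold in the scheme (>=1 and
    >=2 distinct categories in the original scheme, plus >=3 in the
    expanded scheme) and >=1 psychotropic class. A documented severe
    psychiatric condition forces at least 2 points.
    """
    n_categories = len(flags.neuro_categories)
    points = sum(1 for threshold in scheme.neuro_count_rules if n_categories >= threshold)
    if scheme.psychotropic_rule and flags.psychotropic_classes:
        points += 1
    if "severe_psychiatric" in flags.neuro_categories:
        points = max(points, 2)
    return min(points, scheme.n_max)


def score_cardiometabolic(
    panel: BiomarkerPanel,
    flags: PhenotypeFlags,
    scheme: WeightingScheme = ORIGINAL,
) -> int:
    """Cardiometabolic points: TyG band plus one for documented diagnoses."""
    points = bisect.bisect_right(scheme.tyg_thresholds, panel.tyg)
    if flags.cardiometabolic_dx:
        points += 1
    return min(points, scheme.c_max)


def score_renal(
    panel: BiomarkerPanel,
    dialysis: bool = False,
    scheme: WeightingScheme = ORIGINAL,
) -> int:
    """Renal points by CKD stage; dialysis forces the scheme maximum."""
    if dialysis:
        return scheme.dialysis_points
    return scheme.renal_stage_points[panel.ckd_stage]


def total_score(n: int, c: int, r: int, scheme: WeightingScheme = ORIGINAL) -> int:
    """Additive composite; domain bounds are enforced."""
    for value, upper, label in ((n, scheme.n_max, "N"), (c, scheme.c_max, "C"),
                                (r, scheme.r_max, "R")):
        if not 0 <= value <= upper:
            raise ValueError(f"{label} points {value} outside [0, {upper}]")
    return n + c + r


def categorize(total: int, scheme: WeightingScheme = ORIGINAL) -> str:
    """Risk category: low 0-3, moderate 4-6, high 7-10 on the original scale."""
    if not 0 <= total <= scheme.total_max:
        raise ValueError(f"total {total} outside [0, {scheme.total_max}]")
    low_max, moderate_max = scheme.category_bounds()
    if total <= low_max:
        return "low"
    if total <= moderate_max:
        return "moderate"
    return "high"


def classify_group(panel: BiomarkerPanel, flags: PhenotypeFlags) -> str:
    """Descriptive multimorbidity context.

    cardiometabolic: >=1 cardiometabolic diagnosis with preserved renal
    function (eGFR >= 60); renometabolic: cardiometabolic diagnosis with
    eGFR < 60; other: everything else.
    """
    if flags.cardiometabolic_dx:
        if panel.egfr < REDUCED_RENAL_EGFR:
            return "renometabolic"
        return "cardiometabolic"
    return "other"


def score_record(
    record: PatientRecord,
    dictionaries: Sequence[KeywordDictionary],
    scheme: WeightingScheme = ORIGINAL,
) -> tuple[DomainScores, BiomarkerPanel, PhenotypeFlags]:
    """Score one complete-case record under a weighting scheme."""
    panel = biomarker_panel(record)
    flags = extract_flags(record, dictionaries)
    n = score_neuro(flags, scheme)
    c = score_cardiometabolic(panel, flags, scheme)
    r = score_renal(panel, flags.dialysis_documented, scheme)
    total = total_score(n, c, r, scheme)
    scores = DomainScores(
        patient_id=record.patient_id,
        n_points=n,
        c_points=c,
        r_points=r,
        total=total,
        scheme=scheme.name,
        category=categorize(total, scheme),
        group=classify_group(panel, flags),
    )
    return scores, panel, flags


def score_cohort(
    records: Iterable[PatientRecord],
    dictionaries: Sequence[KeywordDictionary] | None = None,
    scheme: WeightingScheme = ORIGINAL,
) -> pd.DataFrame:
    """Score a cohort; returns one row per patient.

    Columns: patient_id, group, n_points, c_points, r_points, total,
    category, plus the biomarkers (egfr, ckd_stage, tyg, uacr) and the raw
    covariates used by the analytics layer.
    """
    if dictionaries is None:
        dictionaries = default_dictionaries()
    rows = []
    for record in records:
        scores, panel, flags = score_record(record, dictionaries, scheme)
        rows.append(
            {
                "patient_id": scores.patient_id,
                "group": scores.group,
                "n_points": scores.n_points,
                "c_points": scores.c_points,
                "r_points": scores.r_points,
                "total": scores.total,
                "category": scores.category,
                "scheme": scores.scheme,
                "egfr": panel.egfr,
                "ckd_stage": panel.ckd_stage,
                "tyg": panel.tyg,
                "uacr": panel.uacr,
                "age": record.age,
                "sex": record.sex,
                "n_medications": record.n_medications,
                "dialysis": flags.dialysis_documented,
            }
        )
    return pd.DataFrame(rows)
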