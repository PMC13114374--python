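"""Text-derived Charlson Comorbidity Index proxy.

Only Charlson categories reliably detectable from free-text diagnoses are
implemented (heart failure, cerebrovascular disease, dementia, chronic
pulmonary disease, diabetes, malignancy), plus moderate/severe renal
disease defined objectively as eGFR < 60 mL/min/1.73 m^2 or documented
dialysis. Absent categories contribute zero — this is a proxy for
contextual benchmarking, not a full administrative CCI. Diabetes is scored
as uncomplicated (weight 1); no complication logic is applied.

Age adjustment follows the original framework: 0 points under 50, then one
point per decade band (50-59 -> 1, 60-69 -> 2, 70-79 -> 3, >= 80 -> 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import AbstractSet

from .biomarkers import BiomarkerPanel
from .phenotyping import PhenotypeFlags

__all__ = ["CHARLSON_WEIGHTS", "CharlsonResult", "flag_charlson", "age_points", "compute_cci"]

#: original Charlson weights for the implemented (text-detectable) taxonomy
CHARLSON_WEIGHTS: dict[str, int] = {
    "chf": 1,
    "cerebrovascular": 1,
    "dementia": 1,
    "pulmonary": 1,
    "diabetes": 1,
    "malignancy": 2,
    "renal_disease": 2,
}

_RENAL_DISEASE_EGFR = 60.0


@dataclass(frozen=True)
class CharlsonResult:
    patient_id: str
    flagged_categories: frozenset[str]
    cci: int
    age_points: int

    @property
    def cci_age_adjusted(self) -> int:
        return self.cci + self.age_points


def flag_charlson(flags: PhenotypeFlags, panel: BiomarkerPanel) -> frozenset[str]:
    """Union of text-flagged categories and the objective renal-disease flag."""
    categories = set(flags.charlson_categories)
    if panel.egfr < _RENAL_DISEASE_EGFR or flags.dialysis_documented:
        categories.add("renal_disease")
    return frozenset(categories)


def age_points(age: float) -> int:
    """Age adjustment: +1 per decade from 50-59, capped at 4 for >= 80."""
    if age < 50:
        return 0
    return min(int((age - 40) // 10), 4)


def compute_cci(
    categories: AbstractSet[str], age: float, patient_id: str = ""
) -> CharlsonResult:
    """Sum original Charlson weights and add the age adjustment."""
    unknown = set(categories) - set(CHARLSON_WEIGHTS)
    if unknown:
        raise ValueError(f"unknown Charlson categories: {sorted(unknown)}")
    cci = sum(CHARLSON_WEIGHTS[c] for c in categories)
    return CharlsonResult(
        patient_id=patient_id,
        flagged_categories=frozenset(categories),
        cci=cci,
        age_points=age_points(age),
    )
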