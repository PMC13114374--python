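"""TyG index, MDRD eGFR and CKD staging from laboratory values.

TyG = ln(triglycerides [mg/dL] x glucose [mg/dL] / 2), a surrogate of
insulin resistance.

eGFR uses the IDMS-traceable 4-variable MDRD equation (coefficient 175),
with the 0.742 female factor and no ethnicity factor:

    eGFR = 175 * creatinine^(-1.154) * age^(-0.203) * (0.742 if female)

in mL/min/1.73 m^2, creatinine in mg/dL. Implementations built on the older
186-coefficient re-expression differ from this one by the constant ratio
186/175; the 175 form is the contemporary standard and is fixed here.

CKD stages follow KDIGO eGFR bands, left-closed at each stage's lower
bound, so eGFR = 60 is G2 (preserved function), eGFR = 15 is G4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import PatientRecord

__all__ = [
    "CKD_STAGES",
    "BiomarkerPanel",
    "compute_tyg",
    "compute_egfr_mdrd",
    "creatinine_from_egfr",
    "ckd_stage",
    "biomarker_panel",
]

#: stages ordered from preserved function to kidney failure
CKD_STAGES = ("G1", "G2", "G3a", "G3b", "G4", "G5")

# (lower bound, stage); bands are [lower, upper)
_STAGE_BOUNDS = (
    (90.0, "G1"),
    (60.0, "G2"),
    (45.0, "G3a"),
    (30.0, "G3b"),
    (15.0, "G4"),
    (0.0, "G5"),
)

_FEMALE_FACTOR = 0.742
_MDRD_COEF = 175.0


@dataclass(frozen=True)
class BiomarkerPanel:
    """Derived biomarkers for one patient."""

    patient_id: str
    tyg: float
    egfr: float
    ckd_stage: str
    uacr: float | None = None


def compute_tyg(triglycerides: float, glucose: float) -> float:
    """TyG index; both inputs in mg/dL and strictly positive."""
    if not triglycerides > 0 or not glucose > 0:
        raise ValueError("triglycerides and glucose must be > 0 for TyG")
    return math.log(triglycerides * glucose / 2.0)


def compute_egfr_mdrd(creatinine: float, age: float, sex: str) -> float:
    """4-variable IDMS-traceable MDRD eGFR (mL/min/1.73 m^2)."""
    if not creatinine > 0 or not age > 0:
        raise ValueError("creatinine and age must be > 0 for eGFR")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    egfr = _MDRD_COEF * creatinine ** -1.154 * age ** -0.203
    if sex == "female":
        egfr *= _FEMALE_FACTOR
    return egfr


def creatinine_from_egfr(egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (mg/dL) that yields ``egfr`` under the MDRD equation.

    Exact inverse of :func:`compute_egfr_mdrd`; used by the synthetic cohort
    generator so that generated records carry only raw labs.
    """
    if not egfr > 0 or not age > 0:
        raise ValueError("egfr and age must be > 0")
    base = _MDRD_COEF * age ** -0.203
    if sex == "female":
        base *= _FEMALE_FACTOR
    return (egfr / base) ** (-1.0 / 1.154)


def ckd_stage(egfr: float) -> str:
    """KDIGO stage for an eGFR value; bands left-closed at the lower bound."""
    if not egfr > 0:
        raise ValueError("egfr must be > 0")
    for lower, stage in _STAGE_BOUNDS:
        if egfr >= lower:
            return stage
    raise AssertionError("unreachable")


def biomarker_panel(record: PatientRecord) -> BiomarkerPanel:
    """Compute the full panel for one complete-case record."""
    missing = [
        name
        for name in ("triglycerides", "glucose", "creatinine")
        if getattr(record, name) is None
    ]
    if missing:
        raise ValueError(
            f"patient {record.patient_id!r}: cannot compute biomarkers, missing {missing}"
        )
    egfr = compute_egfr_mdrd(record.creatinine, record.age, record.sex)
    return BiomarkerPanel(
        patient_id=record.patient_id,
        tyg=compute_tyg(record.triglycerides, record.glucose),
        egfr=egfr,
        ckd_stage=ckd_stage(egfr),
        uacr=record.uacr,
    )
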