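"""Seeded synthetic EMR cohorts with the three-group study structure.

The generator emulates a cohort of three multimorbidity contexts —
cardiometabolic (preserved renal function), renometabolic (reduced renal
function) and a small heterogeneous "other" group — whose biomarker group
means follow the study conditions. Records are structurally identical to
real inputs: only raw fields (creatinine, glucose, triglycerides, free
text) are stored, and every derived quantity (eGFR, TyG, stage) is
recomputed downstream.

Renal function uses a stage-quota design: each group carries exact
per-stratum counts with eGFR drawn uniformly within the stratum band, and
serum creatinine obtained by inverting the MDRD equation against the
sampled age and sex. TyG targets are met by sampling the index directly
and back-solving triglycerides against a log-normal glucose draw.

Diagnosis texts mix Romanian and English surface forms (with diacritics
and mixed case, exercising the normalization path) and include distractor
strings that match no dictionary — a built-in negative control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .biomarkers import creatinine_from_egfr
from .cohort import PatientRecord

__all__ = [
    "ScenarioError",
    "EgfrStratum",
    "GroupScenario",
    "ScenarioConfig",
    "load_scenario",
    "default_scenario",
    "generate",
    "inject_missingness",
]

# physiologic bounds enforced on generated labs
CREATININE_BOUNDS = (0.3, 15.0)
GLUCOSE_BOUNDS = (50.0, 500.0)
TRIGLYCERIDE_BOUNDS = (30.0, 1000.0)


class ScenarioError(ValueError):
    """Invalid or infeasible scenario configuration."""


@dataclass(frozen=True)
class EgfrStratum:
    count: int
    lo: float
    hi: float
    dialysis: bool = False

    def __post_init__(self) -> None:
        if self.count < 0 or not 0 < self.lo < self.hi:
            raise ScenarioError(f"invalid eGFR stratum {self}")


@dataclass(frozen=True)
class GroupScenario:
    name: str  # cardiometabolic | renometabolic | other
    size: int
    egfr_strata: tuple[EgfrStratum, ...]
    age_mean: float
    age_sd: float
    age_lo: float
    age_hi: float
    tyg_mean: float
    tyg_sd: float
    tyg_lo: float
    tyg_hi: float
    glucose_median: float
    glucose_sigma: float
    meds_mean: float
    uacr_mean: float
    uacr_sigma: float
    uacr_missing: float
    cardiometabolic_dx: Mapping[str, float] = field(default_factory=dict)
    charlson_dx: Mapping[str, float] = field(default_factory=dict)
    neuro_prevalence: Mapping[str, float] = field(default_factory=dict)
    psychotropic_prevalence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ScenarioError(f"group {self.name!r}: size must be positive")
        if sum(s.count for s in self.egfr_strata) != self.size:
            raise ScenarioError(f"group {self.name!r}: stratum counts must sum to size")
        for probs in (self.cardiometabolic_dx, self.charlson_dx,
                      self.neuro_prevalence, self.psychotropic_prevalence):
            for key, p in probs.items():
                if not 0 <= p <= 1:
                    raise ScenarioError(f"group {self.name!r}: probability {key}={p}")
        # feasibility: group labels must be recoverable from the generated data
        if self.name == "cardiometabolic":
            if not self.cardiometabolic_dx:
                raise ScenarioError("cardiometabolic group needs >=1 diagnosis keyword")
            if any(s.lo < 60 for s in self.egfr_strata):
                raise ScenarioError(
                    "cardiometabolic group requires preserved renal function (eGFR >= 60)"
                )
        elif self.name == "renometabolic":
            if not self.cardiometabolic_dx:
                raise ScenarioError("renometabolic group needs >=1 diagnosis keyword")
            if any(s.hi >= 60 for s in self.egfr_strata):
                raise ScenarioError(
                    "renometabolic group requires reduced renal function (eGFR < 60)"
                )
        elif self.name == "other":
            if self.cardiometabolic_dx:
                raise ScenarioError("'other' group must carry no cardiometabolic keyword")
        else:
            raise ScenarioError(f"unknown group name {self.name!r}")

    @property
    def expected_egfr_mean(self) -> float:
        return sum(s.count * (s.lo + s.hi) / 2 for s in self.egfr_strata) / self.size


@dataclass(frozen=True)
class ScenarioConfig:
    groups: tuple[GroupScenario, ...]
    female_prob: float
    diagnosis_surfaces: Mapping[str, Sequence[str]]
    medication_surfaces: Mapping[str, Sequence[str]]
    distractor_diagnoses: tuple[str, ...]
    medication_fillers: tuple[str, ...]
    dialysis_phrase: str
    seed: int = 1

    def scaled(self, factor: int) -> "ScenarioConfig":
        """Scale every group (and its strata) by an integer factor."""
        if factor < 1:
            raise ScenarioError("scale factor must be >= 1")
        groups = tuple(
            replace(
                g,
                size=g.size * factor,
                egfr_strata=tuple(replace(s, count=s.count * factor) for s in g.egfr_strata),
            )
            for g in self.groups
        )
        return replace(self, groups=groups)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load a scenario from a YAML file (same schema as the bundled default)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    groups = []
    for g in raw["groups"]:
        groups.append(
            GroupScenario(
                name=g["name"],
                size=int(g["size"]),
                egfr_strata=tuple(
                    EgfrStratum(
                        count=int(s["count"]),
                        lo=float(s["lo"]),
                        hi=float(s["hi"]),
                        dialysis=bool(s.get("dialysis", False)),
                    )
                    for s in g["egfr_strata"]
                ),
                age_mean=float(g["age"]["mean"]),
                age_sd=float(g["age"]["sd"]),
                age_lo=float(g["age"]["lo"]),
                age_hi=float(g["age"]["hi"]),
                tyg_mean=float(g["tyg"]["mean"]),
                tyg_sd=float(g["tyg"]["sd"]),
                tyg_lo=float(g["tyg"]["lo"]),
                tyg_hi=float(g["tyg"]["hi"]),
                glucose_median=float(g["glucose"]["median"]),
                glucose_sigma=float(g["glucose"]["sigma"]),
                meds_mean=float(g["meds_mean"]),
                uacr_mean=float(g["uacr"]["mean"]),
                uacr_sigma=float(g["uacr"]["sigma"]),
                uacr_missing=float(g["uacr"]["missing"]),
                cardiometabolic_dx=dict(g.get("cardiometabolic_dx") or {}),
                charlson_dx=dict(g.get("charlson_dx") or {}),
                neuro_prevalence=dict(g.get("neuro_prevalence") or {}),
                psychotropic_prevalence=dict(g.get("psychotropic_prevalence") or {}),
            )
        )
    return ScenarioConfig(
        groups=tuple(groups),
        female_prob=float(raw.get("female_prob", 0.5)),
        diagnosis_surfaces={k: tuple(v) for k, v in raw["diagnosis_surfaces"].items()},
        medication_surfaces={k: tuple(v) for k, v in raw["medication_surfaces"].items()},
        distractor_diagnoses=tuple(raw["distractor_diagnoses"]),
        medication_fillers=tuple(raw["medication_fillers"]),
        dialysis_phrase=str(raw["dialysis_phrase"]),
        seed=int(raw.get("seed", 1)),
    )


def default_scenario() -> ScenarioConfig:
    """The bundled scenario with group sizes 48 / 82 / 13."""
    source = resources.files("ncrsi.data").joinpath("default_study.yml")
    with resources.as_file(source) as path:
        return load_scenario(path)


def _clip(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _sample_patient(
    rng: np.random.Generator,
    config: ScenarioConfig,
    group: GroupScenario,
    stratum: EgfrStratum,
    patient_id: str,
) -> PatientRecord:
    egfr = rng.uniform(stratum.lo, stratum.hi)
    age = _clip(rng.normal(group.age_mean, group.age_sd), group.age_lo, group.age_hi)
    sex = "female" if rng.random() < config.female_prob else "male"
    creatinine = _clip(creatinine_from_egfr(egfr, age, sex), *CREATININE_BOUNDS)

    tyg = _clip(rng.normal(group.tyg_mean, group.tyg_sd), group.tyg_lo, group.tyg_hi)
    glucose = _clip(
        rng.lognormal(math.log(group.glucose_median), group.glucose_sigma),
        60.0,
        350.0,
    )
    triglycerides = 2.0 * math.exp(tyg) / glucose
    if not TRIGLYCERIDE_BOUNDS[0] <= triglycerides <= TRIGLYCERIDE_BOUNDS[1]:
        # clamp triglycerides and re-solve glucose so the sampled TyG is kept
        triglycerides = _clip(triglycerides, *TRIGLYCERIDE_BOUNDS)
        glucose = 2.0 * math.exp(tyg) / triglycerides

    n_medications = int(rng.poisson(group.meds_mean))
    if rng.random() < group.uacr_missing:
        uacr = None
    else:
        mu = math.log(group.uacr_mean) - group.uacr_sigma**2 / 2
        uacr = round(float(rng.lognormal(mu, group.uacr_sigma)), 1)

    # --- diagnosis text ---
    dx_parts: list[str] = []
    sampled_cardio = [
        cat for cat, p in group.cardiometabolic_dx.items() if rng.random() < p
    ]
    if group.cardiometabolic_dx and not sampled_cardio:
        # cardio groups are defined by >=1 documented condition
        sampled_cardio = [max(group.cardiometabolic_dx, key=group.cardiometabolic_dx.get)]
    for cat in sampled_cardio:
        dx_parts.append(_pick(rng, config.diagnosis_surfaces[cat]))
    for cat, p in group.charlson_dx.items():
        if rng.random() < p:
            dx_parts.append(_pick(rng, config.diagnosis_surfaces[cat]))
    for cat, p in group.neuro_prevalence.items():
        if rng.random() < p:
            dx_parts.append(_pick(rng, config.diagnosis_surfaces[cat]))
    if rng.random() < 0.6:
        dx_parts.append(_pick(rng, config.distractor_diagnoses))
    if stratum.dialysis:
        dx_parts.append(config.dialysis_phrase)
    if not dx_parts:  # never emit an empty diagnosis field
        dx_parts.append(_pick(rng, config.distractor_diagnoses))
    order = rng.permutation(len(dx_parts))
    diagnosis_text = "; ".join(dx_parts[i] for i in order)

    # --- medication text ---
    med_parts = [
        _pick(rng, config.medication_surfaces[cls])
        for cls, p in group.psychotropic_prevalence.items()
        if rng.random() < p
    ]
    n_fillers = int(rng.integers(1, 4))
    filler_idx = rng.choice(len(config.medication_fillers), size=n_fillers, replace=False)
    med_parts.extend(config.medication_fillers[i] for i in filler_idx)
    medication_text = "; ".join(med_parts)

    return PatientRecord(
        patient_id=patient_id,
        age=round(age, 1),
        sex=sex,
        creatinine=round(creatinine, 3),
        glucose=round(glucose, 1),
        triglycerides=round(triglycerides, 1),
        uacr=uacr,
        n_medications=n_medications,
        diagnosis_text=diagnosis_text,
        medication_text=medication_text,
        dialysis_flag=stratum.dialysis,
    )


def generate(config: ScenarioConfig, seed: int | None = None) -> list[PatientRecord]:
    """Generate a cohort; deterministic for a fixed seed.

    Group membership is recoverable from the generated data alone:
    cardiometabolic records carry >=1 cardiometabolic keyword and
    eGFR >= 60, renometabolic records the keyword and eGFR < 60, and
    "other" records no cardiometabolic keyword at all.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[PatientRecord] = []
    index = 1
    for group in config.groups:
        for stratum in group.egfr_strata:
            for _ in range(stratum.count):
                records.append(
                    _sample_patient(rng, config, group, stratum, f"P{index:05d}")
                )
                index += 1
    return records


_BLANKABLE = (
    "creatinine", "glucose", "triglycerides", "uacr",
    "n_medications", "diagnosis_text", "medication_text",
)


def inject_missingness(
    records: Sequence[PatientRecord],
    rates: Mapping[str, float],
    seed: int = 0,
) -> list[PatientRecord]:
    """Independently blank each eligible field with its rate; seeded."""
    unknown = set(rates) - set(_BLANKABLE)
    if unknown:
        raise ScenarioError(f"cannot inject missingness into fields {sorted(unknown)}")
    for name, rate in rates.items():
        if not 0 <= rate < 1:
            raise ScenarioError(f"rate for {name!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out: list[PatientRecord] = []
    for rec in records:
        changes = {}
        for name, rate in rates.items():
            if rng.random() < rate:
                changes[name] = "" if name.endswith("_text") else None
        out.append(replace(rec, **changes) if changes else rec)
    return out
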