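"""AAP 2017 periodontitis staging and grading rule engine.

Staging (radiographic bone loss, per tooth): Stage I < 15%, Stage II
15-33%, Stage III-IV > 33%; the most severe tooth sets the patient stage.
Stage III vs IV requires clinical criteria outside radiographs, so the two
are reported as a combined III_IV token with a free-text clinician override
slot.

Grading (progression rate): primary criterion is the worst-site bone-loss
percentage divided by age — Grade A < 0.25, Grade B 0.25-1.0, Grade C
> 1.0 — then risk-factor modifiers may upgrade (never downgrade): light
smoking (< 10 cigarettes/day) or controlled diabetes (HbA1c < 7.0%) implies
at least Grade B; heavy smoking (>= 10/day) or poorly controlled diabetes
(HbA1c >= 7.0%) implies Grade C regardless of the primary grade.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import NoAssessableTeethError
from .geometry import RBLMeasurement

#: Stage breakpoints on RBL% — 15 and 33 belong to Stage II.
STAGE_BREAKPOINTS: tuple[float, float] = (15.0, 33.0)
#: Grade breakpoints on the bone-loss%/age ratio — 0.25 and 1.0 belong to B.
GRADE_BREAKPOINTS: tuple[float, float] = (0.25, 1.0)
#: Cigarettes/day at or above which the Grade C modifier triggers.
SMOKING_GRADE_C_THRESHOLD: int = 10
#: HbA1c (%) at or above which diabetes triggers the Grade C modifier.
HBA1C_GRADE_C_THRESHOLD: float = 7.0


class Stage(enum.IntEnum):
    """Severity stage, ordered I < II < III_IV."""

    I = 1
    II = 2
    III_IV = 3

    @property
    def token(self) -> str:
        return self.name


class Grade(enum.IntEnum):
    """Progression grade, ordered A < B < C."""

    A = 1
    B = 2
    C = 3

    @property
    def token(self) -> str:
        return self.name


@dataclass
class PatientRecord:
    """Risk-factor inputs to grading. A diabetic record must carry HbA1c."""

    age: int
    cigarettes_per_day: int = 0
    has_diabetes: bool = False
    hba1c_percent: float | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError("patient age must be >= 18 years")
        if self.cigarettes_per_day < 0:
            raise ValueError("cigarettes_per_day must be non-negative")
        if self.has_diabetes and self.hba1c_percent is None:
            raise ValueError("a diabetic patient record requires hba1c_percent")


@dataclass
class StageResult:
    per_tooth: dict[int, Stage]
    patient_stage: Stage
    worst_tooth: int


@dataclass
class GradeResult:
    max_rbl_percent: float
    bone_loss_age_ratio: float
    primary_grade: Grade
    modifier_grade: Grade
    final_grade: Grade
    rationale: list[str] = field(default_factory=list)


@dataclass
class DiagnosisReport:
    """Full per-patient assessment with every intermediate quantity exposed."""

    stage: StageResult
    grade: GradeResult
    patient: PatientRecord
    per_tooth_rbl: dict[int, float]
    clinician_override: str | None = None  # free text: e.g. Stage III vs IV call

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient": {
                    "age": self.patient.age,
                    "cigarettes_per_day": self.patient.cigarettes_per_day,
                    "has_diabetes": self.patient.has_diabetes,
                    "hba1c_percent": self.patient.hba1c_percent,
                },
                "per_tooth": {
                    str(code): {
                        "rbl_percent": self.per_tooth_rbl[code],
                        "stage": self.stage.per_tooth[code].token,
                    }
                    for code in sorted(self.per_tooth_rbl)
                },
                "patient_stage": self.stage.patient_stage.token,
                "worst_tooth": self.stage.worst_tooth,
                "max_rbl_percent": self.grade.max_rbl_percent,
                "bone_loss_age_ratio": self.grade.bone_loss_age_ratio,
                "primary_grade": self.grade.primary_grade.token,
                "modifier_grade": self.grade.modifier_grade.token,
                "final_grade": self.grade.final_grade.token,
                "rationale": self.grade.rationale,
                "clinician_override": self.clinician_override,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            "Periodontitis assessment (AAP 2017)",
            "-----------------------------------",
            f"Patient: age {self.patient.age}, "
            f"{self.patient.cigarettes_per_day} cigarettes/day, "
            + (
                f"diabetes (HbA1c {self.patient.hba1c_percent}%)"
                if self.patient.has_diabetes
                else "no diabetes"
            ),
            "",
            "Per-tooth radiographic bone loss:",
        ]
        for code in sorted(self.per_tooth_rbl):
            lines.append(
                f"  tooth {code}: RBL {self.per_tooth_rbl[code]:5.1f}%  "
                f"-> Stage {self.stage.per_tooth[code].token}"
            )
        lines += [
            "",
            f"Patient stage: {self.stage.patient_stage.token} "
            f"(worst tooth {self.stage.worst_tooth})",
            f"Bone loss / age ratio: {self.grade.bone_loss_age_ratio:.3f} "
            f"-> primary Grade {self.grade.primary_grade.token}",
            f"Final grade: {self.grade.final_grade.token}",
        ]
        for reason in self.grade.rationale:
            lines.append(f"  - {reason}")
        if self.clinician_override:
            lines.append(f"Clinician override: {self.clinician_override}")
        return "\n".join(lines)


def stage_tooth(
    rbl_percent: float, breakpoints: tuple[float, float] = STAGE_BREAKPOINTS
) -> Stage:
    """Stage one tooth from its RBL%: < 15 -> I, 15-33 -> II, > 33 -> III_IV."""
    if not 0.0 <= rbl_percent <= 100.0:
        raise ValueError(f"rbl_percent {rbl_percent} outside [0, 100]")
    lo, hi = breakpoints
    if rbl_percent < lo:
        return Stage.I
    if rbl_percent <= hi:
        return Stage.II
    return Stage.III_IV


def _rbl_by_tooth(
    measurements: Iterable[RBLMeasurement] | Mapping[int, float],
) -> dict[int, float]:
    if isinstance(measurements, Mapping):
        return {int(k): float(v) for k, v in measurements.items()}
    return {
        m.fdi_code: m.rbl_percent for m in measurements if m.measurable
    }


def stage_patient(
    measurements: Iterable[RBLMeasurement] | Mapping[int, float],
) -> StageResult:
    """Patient stage = stage of the most severe tooth.

    Accepts RBL measurements (unmeasurable teeth are skipped) or a plain
    mapping FDI code -> RBL%. The worst tooth is the one with maximal RBL,
    ties broken toward the lowest FDI code.
    """
    rbls = _rbl_by_tooth(measurements)
    if not rbls:
        raise NoAssessableTeethError("no measurable teeth to stage")
    per_tooth = {code: stage_tooth(r) for code, r in rbls.items()}
    worst = min(sorted(rbls), key=lambda c: (-rbls[c], c))
    return StageResult(
        per_tooth=per_tooth,
        patient_stage=max(per_tooth.values()),
        worst_tooth=worst,
    )


def grade_primary(
    max_rbl_percent: float,
    age: int,
    breakpoints: tuple[float, float] = GRADE_BREAKPOINTS,
) -> tuple[float, Grade]:
    """Primary grade from the bone-loss%/age ratio.

    ratio < 0.25 -> A; 0.25 <= ratio <= 1.0 -> B; ratio > 1.0 -> C.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    if not 0.0 <= max_rbl_percent <= 100.0:
        raise ValueError(f"max_rbl_percent {max_rbl_percent} outside [0, 100]")
    ratio = max_rbl_percent / age
    lo, hi = breakpoints
    if ratio < lo:
        grade = Grade.A
    elif ratio <= hi:
        grade = Grade.B
    else:
        grade = Grade.C
    return ratio, grade


def apply_grade_modifiers(
    primary_grade: Grade,
    patient: PatientRecord,
    smoking_c_threshold: int = SMOKING_GRADE_C_THRESHOLD,
    hba1c_c_threshold: float = HBA1C_GRADE_C_THRESHOLD,
) -> tuple[Grade, Grade, list[str]]:
    """Risk-factor grade modifiers; returns (modifier, final, rationale).

    Modifiers only upgrade: ``final = max(primary, modifier)``. HbA1c of a
    non-diabetic patient is ignored.
    """
    modifier = Grade.A
    rationale: list[str] = []
    cigs = patient.cigarettes_per_day
    if cigs >= smoking_c_threshold:
        modifier = Grade.C
        rationale.append(
            f"smoking >= {smoking_c_threshold} cigarettes/day -> Grade C modifier"
        )
    elif cigs > 0:
        modifier = max(modifier, Grade.B)
        rationale.append(
            f"smoking < {smoking_c_threshold} cigarettes/day -> Grade B modifier"
        )
    if patient.has_diabetes:
        if patient.hba1c_percent >= hba1c_c_threshold:
            modifier = Grade.C
            rationale.append(
                f"diabetes with HbA1c >= {hba1c_c_threshold}% -> Grade C modifier"
            )
        else:
            modifier = max(modifier, Grade.B)
            rationale.append(
                f"diabetes with HbA1c < {hba1c_c_threshold}% -> Grade B modifier"
            )
    final = max(primary_grade, modifier)
    if final > primary_grade:
        rationale.append(
            f"grade upgraded {primary_grade.token} -> {final.token} by risk factors"
        )
    elif not rationale:
        rationale.append("no risk factors: primary grade unchanged")
    return modifier, final, rationale


def diagnose(
    measurements: Iterable[RBLMeasurement] | Mapping[int, float],
    patient: PatientRecord,
) -> DiagnosisReport:
    """Compose staging, primary grading and modifiers into a full report.

    Grading uses the maximum RBL% across measurable teeth (worst site),
    including teeth clamped at 100% for bone loss past the apex.
    """
    rbls = _rbl_by_tooth(measurements)
    stage = stage_patient(rbls)
    max_rbl = max(rbls.values())
    ratio, primary = grade_primary(max_rbl, patient.age)
    modifier, final, rationale = apply_grade_modifiers(primary, patient)
    grade = GradeResult(
        max_rbl_percent=max_rbl,
        bone_loss_age_ratio=ratio,
        primary_grade=primary,
        modifier_grade=modifier,
        final_grade=final,
        rationale=rationale,
    )
    return DiagnosisReport(
        stage=stage, grade=grade, patient=patient, per_tooth_rbl=rbls
    )
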