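"""Synthetic patient cases, raw tables, interpretation items and scripted
agents.

The generator emulates the *structure* the framework consumes — template
histories and physical exams, labs drawn around standard reference
ranges with pathology-typical derangements, abdominal imaging findings
with pathology-consistent descriptors, and procedures consistent with
severity — so every module is testable with no download.  The free text
is plainly synthetic; no attempt is made at clinical prose style.

Everything is fully deterministic under a fixed seed (default 2023).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, model_validator

from .builder import RawAdmissionBundle, RawLabEvent, RawRadiologyNote
from .environment import first_words_summarizer
from .evaluation import GuidelineSpec
from .records import (
    LabResult,
    Modality,
    PatientCase,
    Pathology,
    ProcedureRecord,
    RadiologyReport,
)

DEFAULT_SEED = 2023

#: De-identified, year-shifted MIMIC-style base admission time.
BASE_ADMIT = datetime(2130, 1, 1, 8, 0)

Severity = Literal["uncomplicated", "complicated"]


def load_reference_ranges() -> dict[str, tuple[float, float, str]]:
    path = resources.files("cdmbench").joinpath("data", "reference_ranges.yaml")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    return {name: (float(v[0]), float(v[1]), v[2]) for name, v in raw.items()}


# --------------------------------------------------------------------------
# Templates (plainly synthetic; the HPI never names the pathology)

_HPI_TEMPLATES: dict[Pathology, str] = {
    Pathology.APPENDICITIS: (
        "{age}-year-old {sex} presenting with {dur} hours of periumbilical pain "
        "migrating to the right lower quadrant, accompanied by anorexia and "
        "nausea. No prior abdominal surgery. Reports subjective fever."
    ),
    Pathology.CHOLECYSTITIS: (
        "{age}-year-old {sex} presenting with {dur} hours of constant right "
        "upper quadrant pain radiating to the right shoulder, beginning after "
        "a fatty meal, with nausea and vomiting. Similar but milder episodes "
        "in the past."
    ),
    Pathology.DIVERTICULITIS: (
        "{age}-year-old {sex} presenting with {dur} hours of left lower "
        "quadrant pain, low-grade fever and a change in bowel habit. No "
        "hematochezia. History of constipation."
    ),
    Pathology.PANCREATITIS: (
        "{age}-year-old {sex} presenting with {dur} hours of severe epigastric "
        "pain radiating to the back, with persistent nausea and vomiting. "
        "Reports regular alcohol use. Pain is worse when supine."
    ),
}

_PE_TEMPLATES: dict[Pathology, str] = {
    Pathology.APPENDICITIS: (
        "VS: T 38.1 HR 96 BP 124/78. Abdomen: soft, tenderness to palpation in "
        "the right lower quadrant at McBurney's point with guarding, positive "
        "Rovsing sign. No rebound diffusely. Bowel sounds present."
    ),
    Pathology.CHOLECYSTITIS: (
        "VS: T 38.0 HR 92 BP 130/82. Abdomen: soft, marked right upper "
        "quadrant tenderness with inspiratory arrest on deep palpation "
        "(positive Murphy sign). No jaundice. Bowel sounds normal."
    ),
    Pathology.DIVERTICULITIS: (
        "VS: T 38.2 HR 90 BP 128/80. Abdomen: soft, localized left lower "
        "quadrant tenderness with voluntary guarding, no rebound. No "
        "palpable mass. Bowel sounds slightly diminished."
    ),
    Pathology.PANCREATITIS: (
        "VS: T 37.9 HR 104 BP 118/74. Abdomen: epigastric tenderness with "
        "guarding, no rebound. No flank ecchymosis. Bowel sounds diminished. "
        "Patient leaning forward for relief."
    ),
}

# (exam_name, modality, uncomplicated findings, complicated add-on)
_REPORT_TEMPLATES: dict[Pathology, tuple[str, Modality, str, str]] = {
    Pathology.APPENDICITIS: (
        "CT ABDOMEN AND PELVIS W CONTRAST",
        Modality.CT,
        "The appendix is dilated to {size} mm with wall thickening and "
        "periappendiceal fat stranding. An appendicolith is noted. No free "
        "intraperitoneal air. Remaining bowel loops are unremarkable.",
        " A focal fluid collection adjacent to the appendix is concerning "
        "for perforation with abscess formation.",
    ),
    Pathology.CHOLECYSTITIS: (
        "US ABDOMEN (RIGHT UPPER QUADRANT)",
        Modality.ULTRASOUND,
        "The gallbladder is distended with wall thickening measuring {size} mm, "
        "pericholecystic fluid and multiple shadowing gallstones. Positive "
        "sonographic Murphy sign. The common bile duct is not dilated.",
        " The gallbladder wall is irregular with a focal defect, concerning "
        "for perforation.",
    ),
    Pathology.DIVERTICULITIS: (
        "CT ABDOMEN AND PELVIS W CONTRAST",
        Modality.CT,
        "Multiple sigmoid colon diverticula with segmental wall thickening "
        "over {size} cm and adjacent pericolonic fat stranding. No fistula. "
        "The appendix is normal.",
        " Extraluminal foci of gas and an adjacent rim-enhancing fluid "
        "collection are consistent with perforation and abscess.",
    ),
    Pathology.PANCREATITIS: (
        "CT ABDOMEN W CONTRAST",
        Modality.CT,
        "The pancreas is diffusely enlarged and edematous with peripancreatic "
        "fat stranding and a small amount of peripancreatic fluid. No "
        "pseudocyst. The gallbladder contains stones without wall thickening.",
        " Areas of parenchymal non-enhancement involving roughly {size}% of "
        "the gland are consistent with necrosis.",
    ),
}

_DISCHARGE_DX_PHRASE: dict[Pathology, str] = {
    Pathology.APPENDICITIS: "Acute appendicitis",
    Pathology.CHOLECYSTITIS: "Acute cholecystitis",
    Pathology.DIVERTICULITIS: "Acute diverticulitis",
    Pathology.PANCREATITIS: "Acute pancreatitis",
}

#: direction ("up"/"down") and magnitude (fraction of the reference span)
#: of the pathology-typical lab derangements.
DEFAULT_DERANGEMENTS: dict[Pathology, dict[str, tuple[str, float]]] = {
    Pathology.APPENDICITIS: {
        "white blood cell count": ("up", 0.8),
        "c-reactive protein": ("up", 6.0),
    },
    Pathology.CHOLECYSTITIS: {
        "white blood cell count": ("up", 0.6),
        "c-reactive protein": ("up", 4.0),
        "total bilirubin": ("up", 1.5),
        "alkaline phosphatase": ("up", 0.8),
        "aspartate aminotransferase": ("up", 1.2),
        "alanine aminotransferase": ("up", 1.2),
    },
    Pathology.DIVERTICULITIS: {
        "white blood cell count": ("up", 0.6),
        "c-reactive protein": ("up", 8.0),
    },
    Pathology.PANCREATITIS: {
        "lipase": ("up", 6.0),
        "amylase": ("up", 3.0),
        "white blood cell count": ("up", 0.4),
    },
}

_COMPLICATED_EXTRA: dict[Pathology, dict[str, tuple[str, float]]] = {
    Pathology.APPENDICITIS: {"c-reactive protein": ("up", 12.0)},
    Pathology.CHOLECYSTITIS: {"total bilirubin": ("up", 3.0)},
    Pathology.DIVERTICULITIS: {"lactate": ("up", 1.0)},
    Pathology.PANCREATITIS: {
        "hematocrit": ("up", 0.3),
        "blood urea nitrogen": ("up", 1.0),
        "calcium": ("down", 0.3),
        "lactate": ("up", 1.5),
    },
}

# free-text procedure lines per (pathology, severity); keywords align with
# the guideline procedure predicates
_PROCEDURES: dict[tuple[Pathology, Severity], tuple[str, ...]] = {
    (Pathology.APPENDICITIS, "uncomplicated"): ("Laparoscopic appendectomy",),
    (Pathology.APPENDICITIS, "complicated"): (
        "Laparoscopic appendectomy",
        "Percutaneous drainage of periappendiceal abscess",
    ),
    (Pathology.CHOLECYSTITIS, "uncomplicated"): ("Laparoscopic cholecystectomy",),
    (Pathology.CHOLECYSTITIS, "complicated"): (
        "Laparoscopic cholecystectomy",
        "ERCP with biliary stent placement",
    ),
    (Pathology.DIVERTICULITIS, "uncomplicated"): (),
    (Pathology.DIVERTICULITIS, "complicated"): (
        "Sigmoid colectomy (Hartmann procedure)",
        "Percutaneous drainage of pelvic abscess",
    ),
    (Pathology.PANCREATITIS, "uncomplicated"): (),
    (Pathology.PANCREATITIS, "complicated"): (
        "Percutaneous drainage of pancreatic necrosis",
        "ERCP with sphincterotomy",
    ),
}

_CODED_PROCEDURES: dict[tuple[Pathology, Severity], tuple[str, ...]] = {
    (Pathology.APPENDICITIS, "uncomplicated"): ("0DTJ4ZZ",),
    (Pathology.APPENDICITIS, "complicated"): ("0DTJ4ZZ", "0D9J30Z"),
    (Pathology.CHOLECYSTITIS, "uncomplicated"): ("0FT44ZZ",),
    (Pathology.CHOLECYSTITIS, "complicated"): ("0FT44ZZ", "BF101ZZ"),
    (Pathology.DIVERTICULITIS, "uncomplicated"): (),
    (Pathology.DIVERTICULITIS, "complicated"): ("0DTN0ZZ", "0W9G30Z"),
    (Pathology.PANCREATITIS, "uncomplicated"): (),
    (Pathology.PANCREATITIS, "complicated"): ("0F9G30Z", "BF101ZZ"),
}

_ICD_CODES: dict[Pathology, str] = {
    Pathology.APPENDICITIS: "K3580",
    Pathology.CHOLECYSTITIS: "K810",
    Pathology.DIVERTICULITIS: "K5732",
    Pathology.PANCREATITIS: "K859",
}


class CaseProfile(BaseModel):
    """Generator inputs: same (pathology, severity, seed) -> identical case."""

    pathology: Pathology
    severity: Severity = "uncomplicated"
    seed: int = DEFAULT_SEED
    lab_derangements: Optional[dict[str, tuple[str, float]]] = None
    report_template_id: Optional[str] = None
    procedure_set: Optional[tuple[str, ...]] = None

    def derangements(self) -> dict[str, tuple[str, float]]:
        if self.lab_derangements is not None:
            return dict(self.lab_derangements)
        out = dict(DEFAULT_DERANGEMENTS[self.pathology])
        if self.severity == "complicated":
            out.update(_COMPLICATED_EXTRA[self.pathology])
        return out


def _rng_for(profile: CaseProfile) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [
                int(profile.seed) % (2**31),
                list(Pathology).index(profile.pathology),
                0 if profile.severity == "uncomplicated" else 1,
            ]
        )
    )


def _sample_labs(
    profile: CaseProfile, rng: np.random.Generator
) -> list[LabResult]:
    ranges = load_reference_ranges()
    derange = profile.derangements()
    labs: list[LabResult] = []
    for i, (name, (low, high, unit)) in enumerate(ranges.items()):
        span = high - low
        if name in derange:
            direction, mag = derange[name]
            u = float(rng.uniform(0.1, 1.0))
            if direction == "up":
                value = high + (0.05 + u * mag) * span
            else:
                value = max(low - (0.05 + u * mag) * span, low * 0.1)
        else:
            value = float(rng.uniform(low + 0.1 * span, high - 0.1 * span))
        labs.append(
            LabResult(
                canonical_name=name,
                raw_name=name,
                value=round(float(value), 2),
                unit=unit,
                ref_low=low,
                ref_high=high,
                chart_time=BASE_ADMIT + timedelta(minutes=30 + 3 * i),
                source="laboratory",
            )
        )
    labs.append(
        LabResult(
            canonical_name="blood culture",
            raw_name="blood culture",
            value="No growth to date",
            unit="",
            ref_low=None,
            ref_high=None,
            chart_time=BASE_ADMIT + timedelta(hours=4),
            source="microbiology",
        )
    )
    return labs


@dataclass
class _CaseParts:
    """Unvalidated components; violations are injected at this level."""

    profile: CaseProfile
    hpi: str
    pe: str
    labs: list[LabResult]
    reports: list[RadiologyReport]
    free_text_procedures: tuple[str, ...]
    coded_procedures: tuple[str, ...]
    discharge_dx: str


def _make_parts(profile: CaseProfile) -> _CaseParts:
    if profile.report_template_id not in (None, "default"):
        raise ValueError(f"unknown report template {profile.report_template_id!r}")
    rng = _rng_for(profile)
    age = int(rng.integers(18, 90))
    sex = ["man", "woman"][int(rng.integers(0, 2))]
    dur = int(rng.integers(6, 48))
    size = int(rng.integers(9, 16))
    hpi = _HPI_TEMPLATES[profile.pathology].format(age=age, sex=sex, dur=dur)
    pe = _PE_TEMPLATES[profile.pathology]
    labs = _sample_labs(profile, rng)
    exam_name, modality, findings, extra = _REPORT_TEMPLATES[profile.pathology]
    text = findings.format(size=size)
    if profile.severity == "complicated":
        text += extra.format(size=int(rng.integers(30, 50)))
    reports = [
        RadiologyReport(
            exam_name=exam_name,
            modality=modality,
            region="abdomen",
            chart_time=BASE_ADMIT + timedelta(hours=2),
            findings_text=text,
        ),
        RadiologyReport(
            exam_name="CHEST X-RAY (PA AND LAT)",
            modality=Modality.RADIOGRAPH,
            region="chest",
            chart_time=BASE_ADMIT + timedelta(hours=1),
            findings_text="No acute cardiopulmonary process. Normal heart size.",
        ),
    ]
    procs = (
        profile.procedure_set
        if profile.procedure_set is not None
        else _PROCEDURES[(profile.pathology, profile.severity)]
    )
    dx = _DISCHARGE_DX_PHRASE[profile.pathology]
    if profile.severity == "complicated":
        dx += " with perforation" if profile.pathology != Pathology.PANCREATITIS else " with necrosis"
    return _CaseParts(
        profile=profile,
        hpi=hpi,
        pe=pe,
        labs=labs,
        reports=reports,
        free_text_procedures=tuple(procs),
        coded_procedures=_CODED_PROCEDURES[(profile.pathology, profile.severity)],
        discharge_dx=dx,
    )


def _case_id(profile: CaseProfile) -> str:
    return f"{profile.pathology.value[:4]}-{profile.severity[:4]}-{profile.seed}"


def generate_case(profile: CaseProfile) -> PatientCase:
    """Generate one synthetic PatientCase satisfying every case invariant."""
    parts = _make_parts(profile)
    procedures = [
        ProcedureRecord(code=c, source="coded_table") for c in parts.coded_procedures
    ]
    if parts.free_text_procedures:
        procedures.append(
            ProcedureRecord(
                free_text="; ".join(parts.free_text_procedures),
                source="discharge_summary",
            )
        )
    return PatientCase(
        case_id=_case_id(profile),
        pathology=profile.pathology,
        hpi_text=parts.hpi,
        physical_exam_text=parts.pe,
        labs=parts.labs,
        reports=parts.reports,
        procedures=procedures,
        discharge_diagnosis_text=f"1. {parts.discharge_dx}\n2. Hypertension",
    )


def generate_cases(
    n_per_pathology: int,
    seed: int = DEFAULT_SEED,
    complicated_every: int = 3,
) -> list[PatientCase]:
    """A balanced synthetic cohort; every ``complicated_every``-th case of
    each pathology is a complicated presentation."""
    cases = []
    for pathology in Pathology:
        for i in range(n_per_pathology):
            severity: Severity = (
                "complicated" if complicated_every and (i + 1) % complicated_every == 0
                else "uncomplicated"
            )
            cases.append(
                generate_case(
                    CaseProfile(
                        pathology=pathology, severity=severity, seed=seed + i
                    )
                )
            )
    return cases


# --------------------------------------------------------------------------
# Raw MIMIC-shaped tables

VIOLATION_REASONS: tuple[str, ...] = (
    "dual_pathology_codes",
    "secondary_discharge_diagnosis",
    "pathology_in_hpi",
    "no_physical_exam",
    "no_labs",
    "no_abdominal_imaging",
)


def _compose_discharge_summary(
    parts: _CaseParts, include_pe: bool = True, hpi_override: Optional[str] = None
) -> str:
    procs = "; ".join(parts.free_text_procedures) if parts.free_text_procedures else "None"
    sections = [
        "Chief Complaint:\nabdominal pain",
        f"Major Surgical or Invasive Procedure:\n{procs}",
        f"History of Present Illness:\n{hpi_override or parts.hpi}",
    ]
    if include_pe:
        sections.append(f"Physical Exam:\n{parts.pe}")
    sections += [
        f"Discharge Diagnosis:\n1. {parts.discharge_dx}\n2. Hypertension",
        "Discharge Condition:\nStable, ambulating, tolerating oral intake.",
    ]
    return "\n\n".join(sections)


def _radiology_note(report: RadiologyReport) -> RawRadiologyNote:
    text = (
        f"EXAMINATION: {report.exam_name}\n"
        "TECHNIQUE: Standard protocol.\n"
        f"FINDINGS: {report.findings_text}\n"
        "IMPRESSION: Findings correlate with the clinical presentation."
    )
    return RawRadiologyNote(
        exam_name=report.exam_name,
        chart_time=report.chart_time,
        text=text,
        hadm_id=None,  # set by caller
    )


def _bundle_from_parts(
    parts: _CaseParts,
    patient_id: str,
    admission_id: str,
    icd_codes: Sequence[str],
    with_labs: bool = True,
    reports: Optional[Sequence[RadiologyReport]] = None,
    hpi_override: Optional[str] = None,
    include_pe: bool = True,
    discharge_dx_override: Optional[str] = None,
) -> RawAdmissionBundle:
    summary = _compose_discharge_summary(parts, include_pe, hpi_override)
    if discharge_dx_override is not None:
        summary = summary.replace(
            f"Discharge Diagnosis:\n1. {parts.discharge_dx}\n2. Hypertension",
            f"Discharge Diagnosis:\n{discharge_dx_override}",
        )
    lab_events = []
    micro_events = []
    if with_labs:
        for lab in parts.labs:
            event = RawLabEvent(
                name=lab.raw_name,
                value=lab.value,
                unit=lab.unit,
                ref_low=lab.ref_low,
                ref_high=lab.ref_high,
                chart_time=lab.chart_time,
                hadm_id=admission_id,
                source=lab.source,
            )
            (micro_events if lab.source == "microbiology" else lab_events).append(event)
        # a repeated first test later in the stay: the builder must keep
        # only the chronologically first entry
        first = parts.labs[0]
        lab_events.append(
            RawLabEvent(
                name=first.raw_name,
                value=round(float(first.value) * 1.1, 2)
                if isinstance(first.value, float)
                else first.value,
                unit=first.unit,
                ref_low=first.ref_low,
                ref_high=first.ref_high,
                chart_time=first.chart_time + timedelta(hours=6),
                hadm_id=admission_id,
                source="laboratory",
            )
        )
    notes = []
    for report in reports if reports is not None else parts.reports:
        note = _radiology_note(report)
        notes.append(
            RawRadiologyNote(
                exam_name=note.exam_name,
                chart_time=note.chart_time,
                text=note.text,
                hadm_id=admission_id,
            )
        )
    return RawAdmissionBundle(
        patient_id=patient_id,
        admission_id=admission_id,
        admit_time=BASE_ADMIT,
        icd_diagnoses=tuple((c, 10) for c in icd_codes),
        discharge_summary_text=summary,
        lab_events=tuple(lab_events),
        microbiology_events=tuple(micro_events),
        radiology_notes=tuple(notes),
        coded_procedures=parts.coded_procedures,
    )


def generate_raw_tables(
    n_per_pathology: int,
    seed: int = DEFAULT_SEED,
    violation_plan: Optional[Sequence[str]] = None,
) -> list[RawAdmissionBundle]:
    """Emit MIMIC-IV-shaped admission bundles.

    ``violation_plan`` injects one extra admission per listed reason, each
    tripping exactly one dataset-builder exclusion rule.
    """
    if n_per_pathology < 0:
        raise ValueError("n_per_pathology must be >= 0")
    bundles: list[RawAdmissionBundle] = []
    counter = 0
    for pathology in Pathology:
        for i in range(n_per_pathology):
            severity: Severity = "complicated" if (i + 1) % 3 == 0 else "uncomplicated"
            profile = CaseProfile(pathology=pathology, severity=severity, seed=seed + i)
            parts = _make_parts(profile)
            counter += 1
            bundles.append(
                _bundle_from_parts(
                    parts,
                    patient_id=f"p{counter:05d}",
                    admission_id=f"a{counter:05d}",
                    icd_codes=[_ICD_CODES[pathology]],
                )
            )
    for reason in violation_plan or ():
        if reason not in VIOLATION_REASONS:
            raise ValueError(f"unknown violation {reason!r}")
        counter += 1
        profile = CaseProfile(pathology=Pathology.APPENDICITIS, seed=seed + 9000 + counter)
        parts = _make_parts(profile)
        pid, aid = f"p{counter:05d}", f"v-{reason}"
        if reason == "dual_pathology_codes":
            bundles.append(
                _bundle_from_parts(parts, pid, aid, icd_codes=["K3580", "K859"])
            )
        elif reason == "secondary_discharge_diagnosis":
            bundles.append(
                _bundle_from_parts(
                    parts, pid, aid, icd_codes=["K3580"],
                    discharge_dx_override="1. Sepsis\n2. Acute appendicitis",
                )
            )
        elif reason == "pathology_in_hpi":
            bundles.append(
                _bundle_from_parts(
                    parts, pid, aid, icd_codes=["K3580"],
                    hpi_override=parts.hpi + " Transferred with known appendicitis.",
                )
            )
        elif reason == "no_physical_exam":
            bundles.append(
                _bundle_from_parts(parts, pid, aid, icd_codes=["K3580"], include_pe=False)
            )
        elif reason == "no_labs":
            bundles.append(
                _bundle_from_parts(parts, pid, aid, icd_codes=["K3580"], with_labs=False)
            )
        elif reason == "no_abdominal_imaging":
            bundles.append(
                _bundle_from_parts(
                    parts, pid, aid, icd_codes=["K3580"],
                    reports=[r for r in parts.reports if r.region != "abdomen"],
                )
            )
    return bundles


def write_raw_tables(
    bundles: Sequence[RawAdmissionBundle], directory: Union[str, Path]
) -> None:
    """Write bundles out as the MIMIC-style CSV tables the builder reads."""
    import pandas as pd

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    item_ids: dict[str, str] = {}

    def item_id(name: str) -> str:
        if name not in item_ids:
            item_ids[name] = f"lab{len(item_ids) + 1:04d}"
        return item_ids[name]

    adm, dx, lab, mic, proc, disc, rad = [], [], [], [], [], [], []
    for b in bundles:
        adm.append(
            {
                "subject_id": b.patient_id,
                "hadm_id": b.admission_id,
                "admittime": b.admit_time.isoformat(),
                "dischtime": (b.admit_time + timedelta(days=4)).isoformat(),
            }
        )
        for i, (code, version) in enumerate(b.icd_diagnoses, start=1):
            dx.append(
                {
                    "subject_id": b.patient_id,
                    "hadm_id": b.admission_id,
                    "seq_num": i,
                    "icd_code": code,
                    "icd_version": version,
                }
            )
        for e in b.lab_events:
            lab.append(
                {
                    "subject_id": b.patient_id,
                    "hadm_id": e.hadm_id or "",
                    "itemid": item_id(e.name),
                    "charttime": e.chart_time.isoformat(),
                    "value": e.value,
                    "valueuom": e.unit,
                    "ref_range_lower": "" if e.ref_low is None else e.ref_low,
                    "ref_range_upper": "" if e.ref_high is None else e.ref_high,
                }
            )
        for e in b.microbiology_events:
            mic.append(
                {
                    "subject_id": b.patient_id,
                    "hadm_id": e.hadm_id or "",
                    "test_name": e.name,
                    "charttime": e.chart_time.isoformat(),
                    "value": e.value,
                    "valueuom": e.unit,
                    "ref_range_lower": "",
                    "ref_range_upper": "",
                }
            )
        for code in b.coded_procedures:
            proc.append(
                {
                    "subject_id": b.patient_id,
                    "hadm_id": b.admission_id,
                    "icd_code": code,
                    "icd_version": 10,
                }
            )
        disc.append(
            {
                "subject_id": b.patient_id,
                "hadm_id": b.admission_id,
                "text": b.discharge_summary_text,
            }
        )
        for n in b.radiology_notes:
            rad.append(
                {
                    "subject_id": b.patient_id,
                    "hadm_id": n.hadm_id or "",
                    "exam_name": n.exam_name,
                    "charttime": n.chart_time.isoformat(),
                    "text": n.text,
                }
            )
    pd.DataFrame(adm).to_csv(d / "admissions.csv", index=False)
    pd.DataFrame(dx).to_csv(d / "diagnoses_icd.csv", index=False)
    pd.DataFrame(lab).to_csv(d / "labevents.csv", index=False)
    pd.DataFrame(
        [{"itemid": v, "label": k} for k, v in item_ids.items()]
    ).to_csv(d / "d_labitems.csv", index=False)
    pd.DataFrame(mic).to_csv(d / "microbiologyevents.csv", index=False)
    pd.DataFrame(proc).to_csv(d / "procedures_icd.csv", index=False)
    pd.DataFrame(disc).to_csv(d / "discharge.csv", index=False)
    pd.DataFrame(rad).to_csv(d / "radiology.csv", index=False)


# --------------------------------------------------------------------------
# Interpretation task fixtures


class InterpretationItem(BaseModel):
    test: str
    value: float
    ref_low: float
    ref_high: float
    gold_label: Literal["below", "within", "above"]

    @model_validator(mode="after")
    def _consistent(self) -> "InterpretationItem":
        if self.value < self.ref_low:
            expected = "below"
        elif self.value > self.ref_high:
            expected = "above"
        else:
            expected = "within"
        if expected != self.gold_label:
            raise ValueError(
                f"gold label {self.gold_label} inconsistent with value "
                f"{self.value} vs [{self.ref_low}, {self.ref_high}]"
            )
        return self


def generate_interpretation_set(
    n: int, seed: int = DEFAULT_SEED
) -> list[InterpretationItem]:
    """Roughly label-balanced below/within/above items, including boundary
    values (value exactly equal to a bound is within, inclusive bounds)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed % (2**31))
    ranges = list(load_reference_ranges().items())
    items: list[InterpretationItem] = []
    for i in range(n):
        name, (low, high, _unit) = ranges[int(rng.integers(0, len(ranges)))]
        span = high - low
        target = ("below", "within", "above")[i % 3]
        if target == "below":
            value = round(low - 0.05 * span - float(rng.uniform(0, span)), 2)
        elif target == "above":
            value = round(high + 0.05 * span + float(rng.uniform(0, span)), 2)
        elif i % 30 == 1:  # boundary case: value equals a bound -> within
            value = low if (i % 2) else high
        else:
            value = round(float(rng.uniform(low + 0.05 * span, high - 0.05 * span)), 2)
        if value < low:
            gold = "below"
        elif value > high:
            gold = "above"
        else:
            gold = "within"
        items.append(
            InterpretationItem(
                test=name, value=value, ref_low=low, ref_high=high, gold_label=gold
            )
        )
    return items


# --------------------------------------------------------------------------
# Scripted agents


class ScriptedAgent:
    """Deterministic text-in/text-out agent replaying a fixed script.

    Entries may be well-formed or deliberately malformed responses.  When
    the script is exhausted before the episode terminates, the agent emits
    a configurable fallback final-diagnosis turn.  A trivial first-k-words
    summarizer backs the summarization protocol.
    """

    def __init__(
        self,
        script: Sequence[str],
        fallback: str = (
            "Final Diagnosis: undifferentiated abdominal pain\n"
            "Treatment: supportive care with fluids, pain management and monitoring"
        ),
        summarize_words: int = 30,
    ) -> None:
        self._script = list(script)
        self._i = 0
        self.fallback = fallback
        self._summarize = first_words_summarizer(summarize_words)

    def __call__(self, prompt: str, stop: Sequence[str] = ()) -> str:
        if self._i < len(self._script):
            response = self._script[self._i]
            self._i += 1
            return response
        return self.fallback

    def summarize(self, text: str) -> str:
        return self._summarize(text)

    def set_seed(self, seed: int) -> None:  # deterministic: the hint is ignored
        pass


def scripted_agent(policy: Sequence[str], **kwargs) -> ScriptedAgent:
    """Build a deterministic agent from an ordered action script."""
    return ScriptedAgent(policy, **kwargs)


def random_script(
    rng: np.random.Generator,
    n_actions: Optional[int] = None,
    end_with_final: bool = True,
) -> list[str]:
    """A randomized agent script mixing well-formed requests, free-text
    prose, hallucinated tools, empty responses and a terminating
    diagnosis — the workload for protocol-conformance checks."""
    pool = [
        "Thoughts: examine the patient.\nAction: Physical Examination\nAction Input: full exam",
        "Thoughts: check inflammation.\nAction: Laboratory Tests\nAction Input: complete blood count",
        "Thoughts: enzymes.\nAction: Laboratory Tests\nAction Input: lipase, amylase",
        "Thoughts: image.\nAction: Imaging\nAction Input: CT abdomen",
        "Thoughts: image.\nAction: Imaging\nAction Input: abdominal ultrasound",
        "Thoughts: look elsewhere.\nAction: Imaging\nAction Input: chest x-ray",
        "I would like to perform a physical examination",
        "Please order some laboratory tests for this patient",
        "Thoughts: try something else.\nAction: Crystal Ball\nAction Input: the future",
        "Thoughts: consult.\nAction: Colonoscopy\nAction Input: full",
        "",
        "Thoughts: image again.\nAction: Imaging\nAction Input: CT abdomen\n"
        "Observation: the scan shows nothing",
    ]
    if n_actions is None:
        n_actions = int(rng.integers(1, 8))
    script = [pool[int(rng.integers(0, len(pool)))] for _ in range(n_actions)]
    if end_with_final:
        finals = [
            "Thoughts: done.\nFinal Diagnosis: acute appendicitis\nTreatment: appendectomy and antibiotics",
            "Thoughts: done.\nFinal Diagnosis: acute pancreatitis\nTreatment: fluids, pain management, monitoring",
            "Final Diagnosis: acute cholecystitis",  # malformed: no treatment
        ]
        script.append(finals[int(rng.integers(0, len(finals)))])
    return script


def omniscient_script(case: PatientCase, guideline: GuidelineSpec) -> list[str]:
    """The guideline-following script for one case: physical examination
    first, one request covering every required lab category, abdominal
    imaging in the modality the case actually has, then the gold diagnosis
    with every expected treatment mentioned."""
    pg = guideline.pathologies[case.pathology]
    tests = [t for members in pg.lab_categories.values() for t in members]
    abdominal = [r for r in case.reports if r.region == "abdomen"]
    modality = abdominal[0].modality.value if abdominal else "CT"
    treatments = []
    for t in pg.essential_treatments:
        if t == "support":
            treatments.append(
                "intravenous fluids, pain management with analgesia, and close monitoring"
            )
        else:
            treatments.append(t)
    for t in pg.case_specific_treatments:
        treatments.append(t)
    return [
        "Thoughts: start with a complete physical examination.\n"
        "Action: Physical Examination\nAction Input: full exam",
        "Thoughts: order the guideline laboratory categories.\n"
        f"Action: Laboratory Tests\nAction Input: {', '.join(tests)}",
        "Thoughts: image the abdomen.\n"
        f"Action: Imaging\nAction Input: {modality} abdomen",
        "Thoughts: the workup is diagnostic.\n"
        f"Final Diagnosis: acute {case.pathology.value}\n"
        f"Treatment: {'; '.join(treatments)}",
    ]
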