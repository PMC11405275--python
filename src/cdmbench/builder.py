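"""Dataset construction from raw MIMIC-IV-style relational tables.

The pipeline turns per-admission bundles of raw records into servable
:class:`~cdmbench.records.PatientCase` objects:

1. ICD filter — keep admissions coded for exactly one target pathology;
2. discharge-diagnosis check — the very first diagnosis listed in the
   discharge summary's discharge-diagnosis section must be the candidate
   pathology;
3. section extraction — history of present illness and physical exam are
   pulled from the discharge summary; admissions whose HPI mentions the
   pathology (established diagnoses, transfers) or that lack a physical
   exam are dropped;
4. data collection — labs/microbiology and radiology findings within the
   admission or up to 24 h before it (if not attributable to another
   admission), first entry per repeated test, findings-only report text;
5. final cleaning — drop admissions with no labs or no abdominal
   imaging; censor residual pathology mentions to ``___``.

Every stage's in/out counts and per-admission exclusion reasons land in a
:class:`BuildReport` whose counts telescope exactly.

The same module assembles the full-information (FI) prompt: HPI, physical
exam, guideline-relevant labs, then abdominal imaging in chart order,
summarized stepwise when the token budget would overflow.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .environment import Summarizer, TokenBudget, first_words_summarizer
from .evaluation import GuidelineSpec
from .lexicon import (
    AmbiguousRequestError,
    DiagnosisLexicon,
    ImagingLexicon,
    LabLexicon,
    classify_imaging_request,
    match_diagnosis,
    normalize,
)
from .records import (
    LabResult,
    PatientCase,
    Pathology,
    ProcedureRecord,
    RadiologyReport,
    censor_pathology_mentions,
    contains_pathology_mention,
)

# --------------------------------------------------------------------------
# Raw types


@dataclass(frozen=True)
class RawLabEvent:
    name: str
    value: Union[float, str]
    unit: str
    ref_low: Optional[float]
    ref_high: Optional[float]
    chart_time: datetime
    hadm_id: Optional[str]  # None = not linked to any admission
    source: str = "laboratory"


@dataclass(frozen=True)
class RawRadiologyNote:
    exam_name: str
    chart_time: datetime
    text: str
    hadm_id: Optional[str]


@dataclass(frozen=True)
class RawAdmissionBundle:
    patient_id: str
    admission_id: str
    admit_time: datetime
    icd_diagnoses: tuple[tuple[str, int], ...]  # (code, icd version), as recorded
    discharge_summary_text: str
    lab_events: tuple[RawLabEvent, ...] = ()
    microbiology_events: tuple[RawLabEvent, ...] = ()
    radiology_notes: tuple[RawRadiologyNote, ...] = ()
    coded_procedures: tuple[str, ...] = ()
    # [start, end] spans of the same patient's *other* admissions, used to
    # decide whether an unlinked pre-admission event belongs elsewhere
    other_admission_windows: tuple[tuple[datetime, datetime], ...] = ()


@dataclass
class StageCount:
    name: str
    n_in: int
    n_out: int


@dataclass
class BuildReport:
    """QC surface: telescoping per-stage counts and exclusion reasons."""

    stages: list[StageCount] = field(default_factory=list)
    drop_reasons: Counter = field(default_factory=Counter)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (admission_id, reason)
    report_drops: list[tuple[str, str]] = field(default_factory=list)  # (exam_name, reason)

    def record_drop(self, admission_id: str, reason: str) -> None:
        self.drop_reasons[reason] += 1
        self.dropped.append((admission_id, reason))

    def validate(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if prev.n_out != cur.n_in:
                raise ValueError(
                    f"counts do not telescope: {prev.name} out {prev.n_out} "
                    f"!= {cur.name} in {cur.n_in}"
                )
        total_dropped = sum(s.n_in - s.n_out for s in self.stages)
        if total_dropped != sum(self.drop_reasons.values()):
            raise ValueError("exclusion reasons do not sum to dropped count")

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "in": s.n_in, "out": s.n_out} for s in self.stages
            ],
            "drop_reasons": dict(sorted(self.drop_reasons.items())),
            "dropped": sorted(self.dropped),
            "report_drops": sorted(self.report_drops),
        }


# --------------------------------------------------------------------------
# ICD filtering


def load_icd_code_sets(path: Union[str, Path, None] = None) -> dict[Pathology, list[str]]:
    if path is None:
        path = Path(str(resources.files("cdmbench").joinpath("data", "icd_codes.yaml")))
    raw = yaml.safe_load(Path(path).read_text())
    return {
        Pathology(p): [c for key in ("icd9", "icd10") for c in spec.get(key, [])]
        for p, spec in raw.items()
    }


def _code_matches(code: str, prefixes: Sequence[str]) -> bool:
    c = code.replace(".", "").upper()
    return any(c.startswith(p.replace(".", "").upper()) for p in prefixes)


def filter_target_admissions(
    bundles: Sequence[RawAdmissionBundle],
    icd_code_sets: dict[Pathology, Sequence[str]],
    report: Optional[BuildReport] = None,
) -> list[tuple[RawAdmissionBundle, Pathology]]:
    """Keep admissions coded for exactly one target pathology.

    Admissions whose codes match more than one target are removed; so are
    admissions matching none.
    """
    for pathology, codes in icd_code_sets.items():
        if not codes:
            raise ValueError(f"empty ICD code set for {pathology}")
    kept: list[tuple[RawAdmissionBundle, Pathology]] = []
    for bundle in bundles:
        matched = {
            pathology
            for code, _version in bundle.icd_diagnoses
            for pathology, prefixes in icd_code_sets.items()
            if _code_matches(code, prefixes)
        }
        if len(matched) == 1:
            kept.append((bundle, next(iter(matched))))
        elif report is not None:
            reason = "no_target_code" if not matched else "dual_pathology_codes"
            report.record_drop(bundle.admission_id, reason)
    return kept


# --------------------------------------------------------------------------
# Discharge-summary sections

#: Default header patterns for MIMIC-style discharge summaries; the first
#: four are extracted, the rest only bound the preceding section.
DEFAULT_SECTION_PATTERNS: dict[str, str] = {
    "hpi": r"history of present illness\s*:",
    "physical_exam": r"physical exam(?:ination)?\s*:",
    "discharge_diagnosis": r"discharge diagnos(?:is|es)\s*:",
    "free_text_procedures": r"major surgical or invasive procedure\s*:",
}

_BOUNDARY_PATTERNS: tuple[str, ...] = (
    r"chief complaint\s*:",
    r"past medical history\s*:",
    r"social history\s*:",
    r"family history\s*:",
    r"medications on admission\s*:",
    r"allergies\s*:",
    r"pertinent results\s*:",
    r"(?:brief )?hospital course\s*:",
    r"discharge condition\s*:",
    r"discharge medications\s*:",
    r"discharge instructions\s*:",
    r"discharge disposition\s*:",
    r"followup instructions\s*:",
)


def extract_sections(
    discharge_summary_text: str,
    patterns: Optional[dict[str, str]] = None,
) -> dict[str, str]:
    """Locate discharge-summary sections by configurable header patterns.

    Returns a mapping for whichever of hpi / physical_exam /
    discharge_diagnosis / free_text_procedures are present; absence is
    handled downstream, never an error here.
    """
    patterns = patterns or DEFAULT_SECTION_PATTERNS
    headers: list[tuple[int, int, Optional[str]]] = []
    for name, pat in patterns.items():
        for m in re.finditer(pat, discharge_summary_text, flags=re.IGNORECASE):
            headers.append((m.start(), m.end(), name))
    for pat in _BOUNDARY_PATTERNS:
        for m in re.finditer(pat, discharge_summary_text, flags=re.IGNORECASE):
            headers.append((m.start(), m.end(), None))
    headers.sort()
    sections: dict[str, str] = {}
    for i, (start, end, name) in enumerate(headers):
        if name is None or name in sections:
            continue
        stop = headers[i + 1][0] if i + 1 < len(headers) else len(discharge_summary_text)
        body = discharge_summary_text[end:stop].strip()
        if body:
            sections[name] = body
    return sections


def check_primary_discharge_diagnosis(
    bundle: RawAdmissionBundle,
    candidate: Pathology,
    lexicon: DiagnosisLexicon,
    sections: Optional[dict[str, str]] = None,
) -> tuple[bool, str]:
    """Require the very first diagnosis in the discharge-diagnosis section
    to be the candidate pathology; any other diagnosis written before it
    removes the case."""
    if sections is None:
        sections = extract_sections(bundle.discharge_summary_text)
    dd = sections.get("discharge_diagnosis", "")
    if not dd.strip():
        return False, "no_discharge_diagnosis"
    if match_diagnosis(dd, candidate, lexicon):
        return True, ""
    return False, "secondary_discharge_diagnosis"


# --------------------------------------------------------------------------
# Laboratory and report collection


def _in_window(
    event_time: datetime,
    hadm_id: Optional[str],
    bundle: RawAdmissionBundle,
    window: timedelta,
) -> bool:
    if hadm_id == bundle.admission_id:
        return True
    if hadm_id is not None:
        return False
    # unlinked: within [admit - window, admit], closed on both ends, and
    # not attributable to any other admission of the same patient
    if not (bundle.admit_time - window <= event_time <= bundle.admit_time):
        return False
    return not any(
        start <= event_time <= end for start, end in bundle.other_admission_windows
    )


def collect_labs(
    bundle: RawAdmissionBundle,
    lab_lexicon: Optional[LabLexicon] = None,
    window_hours: float = 24.0,
) -> list[LabResult]:
    """Gather admission labs plus unlinked events up to *window_hours*
    before admission, keeping only the chronologically first entry of each
    repeated test (ties broken by source row order).  Microbiology events
    get the same treatment."""
    window = timedelta(hours=window_hours)
    out: list[LabResult] = []
    seen: set[tuple[str, str]] = set()
    for events, source in (
        (bundle.lab_events, "laboratory"),
        (bundle.microbiology_events, "microbiology"),
    ):
        eligible = [
            e for e in events if _in_window(e.chart_time, e.hadm_id, bundle, window)
        ]
        for _, event in sorted(
            enumerate(eligible), key=lambda ie: (ie[1].chart_time, ie[0])
        ):
            canonical = event.name
            if lab_lexicon is not None:
                canonical = lab_lexicon.synonym_map.get(normalize(event.name), event.name)
            key = (source, canonical)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                LabResult(
                    canonical_name=canonical,
                    raw_name=event.name,
                    value=event.value,
                    unit=event.unit,
                    ref_low=event.ref_low,
                    ref_high=event.ref_high,
                    chart_time=event.chart_time,
                    source=source,  # type: ignore[arg-type]
                )
            )
    return out


_FINDINGS_RE = re.compile(
    r"(?is)\bfindings\s*:\s*(.*?)(?=\b(?:impression|conclusion|comparison|recommendation)s?\s*:|\Z)"
)


def extract_findings(note_text: str) -> str:
    """The descriptive findings section only; impression/conclusion carry
    the radiologist's diagnosis and are discarded."""
    m = _FINDINGS_RE.search(note_text)
    return m.group(1).strip() if m else ""


def collect_reports(
    bundle: RawAdmissionBundle,
    lexicon: ImagingLexicon,
    window_hours: float = 24.0,
    report: Optional[BuildReport] = None,
) -> list[RadiologyReport]:
    """Collect radiology reports under the same 24-h inclusion window,
    classifying each exam name to (modality, region) and keeping only the
    findings section.  Unclassifiable or findings-less notes are dropped
    and logged."""
    window = timedelta(hours=window_hours)
    out: list[RadiologyReport] = []
    for note in bundle.radiology_notes:
        if not _in_window(note.chart_time, note.hadm_id, bundle, window):
            continue
        try:
            classified = classify_imaging_request(note.exam_name, lexicon)
        except AmbiguousRequestError:
            classified = None
        if classified is None:
            if report is not None:
                report.report_drops.append((note.exam_name, "unclassifiable_exam_name"))
            continue
        findings = extract_findings(note.text)
        if not findings:
            if report is not None:
                report.report_drops.append((note.exam_name, "empty_findings"))
            continue
        modality, region = classified
        out.append(
            RadiologyReport(
                exam_name=note.exam_name,
                modality=modality,
                region=region,
                chart_time=note.chart_time,
                findings_text=findings,
            )
        )
    return out


# --------------------------------------------------------------------------
# Case assembly


def assemble_case(
    bundle: RawAdmissionBundle,
    pathology: Pathology,
    sections: dict[str, str],
    labs: Sequence[LabResult],
    reports: Sequence[RadiologyReport],
) -> tuple[Optional[PatientCase], str]:
    """Final cleaning: exclusions, censoring, procedure merge.

    Returns (case, "") or (None, reason).
    """
    hpi = sections.get("hpi", "")
    pe = sections.get("physical_exam", "")
    if not hpi.strip() or contains_pathology_mention(hpi, pathology):
        return None, "pathology_in_hpi" if hpi.strip() else "no_hpi"
    if not pe.strip():
        return None, "no_physical_exam"
    if not labs:
        return None, "no_labs"
    if not any(r.region == "abdomen" for r in reports):
        return None, "no_abdominal_imaging"

    procedures: list[ProcedureRecord] = [
        ProcedureRecord(code=code, source="coded_table")
        for code in bundle.coded_procedures
    ]
    free_text = sections.get("free_text_procedures", "").strip()
    if free_text:
        procedures.append(
            ProcedureRecord(free_text=free_text, source="discharge_summary")
        )

    censored_reports = [
        r.model_copy(
            update={"findings_text": censor_pathology_mentions(r.findings_text, pathology)}
        )
        for r in reports
    ]
    case = PatientCase(
        case_id=bundle.admission_id,
        pathology=pathology,
        hpi_text=hpi,
        physical_exam_text=censor_pathology_mentions(pe, pathology),
        labs=list(labs),
        reports=censored_reports,
        procedures=procedures,
        discharge_diagnosis_text=sections.get("discharge_diagnosis", ""),
    )
    return case, ""


def build_dataset(
    bundles: Sequence[RawAdmissionBundle],
    icd_code_sets: Optional[dict[Pathology, Sequence[str]]] = None,
    lab_lexicon: Optional[LabLexicon] = None,
    imaging_lexicon: Optional[ImagingLexicon] = None,
    diagnosis_lexicon: Optional[DiagnosisLexicon] = None,
    window_hours: float = 24.0,
) -> tuple[list[PatientCase], BuildReport]:
    """Run the full construction pipeline; deterministic for identical
    input bundles."""
    icd_code_sets = icd_code_sets or load_icd_code_sets()
    lab_lexicon = lab_lexicon or LabLexicon.from_yaml()
    imaging_lexicon = imaging_lexicon or ImagingLexicon.from_yaml()
    diagnosis_lexicon = diagnosis_lexicon or DiagnosisLexicon.from_yaml()

    report = BuildReport()
    ordered = sorted(bundles, key=lambda b: b.admission_id)

    candidates = filter_target_admissions(ordered, icd_code_sets, report)
    report.stages.append(StageCount("icd_filter", len(ordered), len(candidates)))

    confirmed: list[tuple[RawAdmissionBundle, Pathology, dict[str, str]]] = []
    for bundle, pathology in candidates:
        sections = extract_sections(bundle.discharge_summary_text)
        keep, reason = check_primary_discharge_diagnosis(
            bundle, pathology, diagnosis_lexicon, sections
        )
        if keep:
            confirmed.append((bundle, pathology, sections))
        else:
            report.record_drop(bundle.admission_id, reason)
    report.stages.append(
        StageCount("discharge_diagnosis", len(candidates), len(confirmed))
    )

    cases: list[PatientCase] = []
    n_in = len(confirmed)
    for bundle, pathology, sections in confirmed:
        labs = collect_labs(bundle, lab_lexicon, window_hours)
        reports = collect_reports(bundle, imaging_lexicon, window_hours, report)
        case, reason = assemble_case(bundle, pathology, sections, labs, reports)
        if case is None:
            report.record_drop(bundle.admission_id, reason)
        else:
            cases.append(case)
    report.stages.append(StageCount("assembly", n_in, len(cases)))
    report.validate()
    return cases, report


# --------------------------------------------------------------------------
# MIMIC-style CSV ingestion


def load_raw_tables(directory: Union[str, Path]) -> list[RawAdmissionBundle]:
    """Read a directory of MIMIC-IV-shaped CSV tables into admission
    bundles (admissions, diagnoses_icd, labevents + d_labitems,
    microbiologyevents, procedures_icd, discharge, radiology)."""
    d = Path(directory)

    def read(name: str) -> pd.DataFrame:
        path = d / f"{name}.csv"
        if path.with_suffix(".csv.gz").exists():
            path = path.with_suffix(".csv.gz")
        return pd.read_csv(path, dtype=str, keep_default_na=False)

    admissions = read("admissions")
    diagnoses = read("diagnoses_icd")
    labevents = read("labevents")
    labitems = read("d_labitems").set_index("itemid")["label"].to_dict()
    micro = read("microbiologyevents")
    procedures = read("procedures_icd")
    discharge = read("discharge").set_index("hadm_id")["text"].to_dict()
    radiology = read("radiology")

    def ts(x: str) -> datetime:
        return datetime.fromisoformat(x)

    def opt(x: str) -> Optional[str]:
        return x if x else None

    def num(x: str) -> Optional[float]:
        return float(x) if x else None

    windows: dict[str, tuple[str, datetime, datetime]] = {}
    for _, row in admissions.iterrows():
        windows[row["hadm_id"]] = (
            row["subject_id"],
            ts(row["admittime"]),
            ts(row["dischtime"]),
        )

    bundles: list[RawAdmissionBundle] = []
    for _, row in admissions.sort_values("hadm_id").iterrows():
        hadm = row["hadm_id"]
        subject = row["subject_id"]
        admit = ts(row["admittime"])
        others = tuple(
            (a - timedelta(hours=24), dd)
            for h, (s, a, dd) in sorted(windows.items())
            if s == subject and h != hadm
        )
        dx = diagnoses[diagnoses["hadm_id"] == hadm].sort_values("seq_num")
        icd = tuple((r["icd_code"], int(r["icd_version"])) for _, r in dx.iterrows())

        def events_for(df: pd.DataFrame, name_col: str, source: str):
            sub = df[
                (df["subject_id"] == subject)
                & ((df["hadm_id"] == hadm) | (df["hadm_id"] == ""))
            ]
            out = []
            for _, e in sub.iterrows():
                raw_name = (
                    labitems.get(e["itemid"], e["itemid"])
                    if name_col == "itemid"
                    else e[name_col]
                )
                value: Union[float, str] = e["value"]
                try:
                    value = float(e["value"])
                except ValueError:
                    pass
                out.append(
                    RawLabEvent(
                        name=raw_name,
                        value=value,
                        unit=e.get("valueuom", ""),
                        ref_low=num(e.get("ref_range_lower", "")),
                        ref_high=num(e.get("ref_range_upper", "")),
                        chart_time=ts(e["charttime"]),
                        hadm_id=opt(e["hadm_id"]),
                        source=source,
                    )
                )
            return tuple(out)

        rads = radiology[
            (radiology["subject_id"] == subject)
            & ((radiology["hadm_id"] == hadm) | (radiology["hadm_id"] == ""))
        ]
        notes = tuple(
            RawRadiologyNote(
                exam_name=r["exam_name"],
                chart_time=ts(r["charttime"]),
                text=r["text"],
                hadm_id=opt(r["hadm_id"]),
            )
            for _, r in rads.iterrows()
        )
        procs = tuple(
            procedures[procedures["hadm_id"] == hadm]["icd_code"].tolist()
        )
        bundles.append(
            RawAdmissionBundle(
                patient_id=subject,
                admission_id=hadm,
                admit_time=admit,
                icd_diagnoses=icd,
                discharge_summary_text=discharge.get(hadm, ""),
                lab_events=events_for(labevents, "itemid", "laboratory"),
                microbiology_events=events_for(micro, "test_name", "microbiology"),
                radiology_notes=notes,
                coded_procedures=procs,
                other_admission_windows=others,
            )
        )
    return bundles


# --------------------------------------------------------------------------
# Full-information prompt assembly


def _load_fi_instructions() -> str:
    return (
        resources.files("cdmbench")
        .joinpath("data", "templates", "fi_instructions.txt")
        .read_text(encoding="utf-8")
    )


@dataclass
class FIPrompt:
    """A structured full-information prompt: instruction text plus tagged
    content spans (hpi, pe, labs, imaging) in presentation order."""

    instructions: str
    spans: list[tuple[str, str]]

    def render(self) -> str:
        parts = [self.instructions] + [text for _, text in self.spans]
        return "\n\n".join(p for p in parts if p)

    def span_texts(self, tag: str) -> list[str]:
        return [text for t, text in self.spans if t == tag]


def build_fi_record(
    case: PatientCase,
    guideline: GuidelineSpec,
    budget: Optional[TokenBudget] = None,
    summarizer: Optional[Summarizer] = None,
) -> FIPrompt:
    """Assemble the full-information prompt for one case.

    Content order: history of present illness, physical examination,
    laboratory results (only tests in the union of the guideline
    categories for the diagnosis and its differentials), abdominal
    imaging by chart time from earliest to latest.  If the prompt
    overflows the budget, each report is summarized individually, then
    all imaging at once, then words are removed from the final imaging
    summary until the diagnosis reserve (25 tokens / 20 words) fits.
    """
    budget = budget or TokenBudget()
    summarizer = summarizer or first_words_summarizer()
    relevant = set(guideline.all_relevant_tests())
    lab_lines = [lab.render() for lab in case.labs if lab.canonical_name in relevant]
    spans: list[tuple[str, str]] = [
        ("hpi", f"History of Present Illness:\n{case.hpi_text}"),
        ("pe", f"Physical Examination:\n{case.physical_exam_text}"),
        ("labs", "Laboratory Results:\n" + "\n".join(lab_lines)),
    ]
    abdominal = sorted(
        (r for r in case.reports if r.region == "abdomen"),
        key=lambda r: r.chart_time,
    )
    for r in abdominal:
        spans.append(("imaging", f"{r.exam_name} findings:\n{r.findings_text}"))
    fi = FIPrompt(instructions=_load_fi_instructions(), spans=spans)

    def over() -> bool:
        return budget.count(fi.render()) > budget.usable

    def safe_summarize(text: str) -> Optional[str]:
        try:
            return summarizer(text)
        except Exception:
            return None

    if over():
        # stage 1: summarize each report individually
        for i, (tag, text) in enumerate(fi.spans):
            if tag == "imaging":
                summary = safe_summarize(text)
                if summary is not None:
                    fi.spans[i] = (tag, summary)
                if not over():
                    break
    if over():
        # stage 2: summarize all imaging at once
        imaging = [t for t in fi.span_texts("imaging")]
        if imaging:
            summary = safe_summarize("\n\n".join(imaging))
            merged = summary if summary is not None else "\n\n".join(imaging)
            fi.spans = [s for s in fi.spans if s[0] != "imaging"] + [("imaging", merged)]
    while over():
        # stage 3: remove words from the final imaging summary
        trimmed = False
        for i in range(len(fi.spans) - 1, -1, -1):
            tag, text = fi.spans[i]
            if tag == "imaging":
                words = text.split()
                if words:
                    fi.spans[i] = (tag, " ".join(words[:-1]))
                    trimmed = True
                break
        if not trimmed:
            break
    return fi
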