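"""Core data model for patient cases and episode transcripts.

A :class:`PatientCase` is one emergency-department admission for acute
abdominal pain: the hidden gold pathology plus everything the simulated
clinical environment may serve to an agent (history of present illness,
physical examination, timestamped laboratory results with reference
ranges, radiology report findings, procedure records).

An :class:`Episode` is the transcript of one agent/environment run over a
case: the parsed turns, served observations, instruction-following error
tallies and the final diagnosis and treatment plan.

Both are serialized to line-oriented record files (one JSON object per
line, optionally gzip-compressed) so large case sets stream.  Hidden
fields — the gold pathology and discharge diagnosis — are stored under a
dedicated ``hidden`` key so environment code can withhold them.
"""

from __future__ import annotations

import gzip
import json
import re
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Pathology(str, Enum):
    """The four target abdominal pathologies."""

    APPENDICITIS = "appendicitis"
    CHOLECYSTITIS = "cholecystitis"
    DIVERTICULITIS = "diverticulitis"
    PANCREATITIS = "pancreatitis"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Terms whose presence in a served text would leak the gold diagnosis.
#: Keyed by pathology; checked case-insensitively.  The pathology name
#: itself is always included.
CENSOR_TERMS: dict[Pathology, tuple[str, ...]] = {
    Pathology.APPENDICITIS: ("appendicitis",),
    Pathology.CHOLECYSTITIS: ("cholecystitis",),
    Pathology.DIVERTICULITIS: ("diverticulitis",),
    Pathology.PANCREATITIS: ("pancreatitis",),
}

#: The string MIMIC-style de-identification uses; gold-pathology mentions
#: surviving dataset construction are replaced with it.
CENSOR_MARK = "___"


def contains_pathology_mention(text: str, pathology: Pathology) -> bool:
    """Case-insensitive scan of *text* for the gold pathology name or a
    configured synonym."""
    low = text.lower()
    return any(term in low for term in CENSOR_TERMS[pathology])


def censor_pathology_mentions(text: str, pathology: Pathology) -> str:
    """Replace every mention of the gold pathology (or synonym) with ``___``."""
    out = text
    for term in CENSOR_TERMS[pathology]:
        out = re.sub(re.escape(term), CENSOR_MARK, out, flags=re.IGNORECASE)
    return out


class Modality(str, Enum):
    CT = "CT"
    ULTRASOUND = "Ultrasound"
    MRI = "MRI"
    RADIOGRAPH = "Radiograph"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class LabResult(BaseModel):
    """A timestamped laboratory or microbiology test result.

    ``value`` keeps whatever the source recorded — a number, or raw text
    such as ``"<0.1"`` or a qualitative culture result.  ``value_num`` is
    the parsed numeric value when the raw value parses as a plain number,
    else ``None``; interpretation tasks need the number, transcripts need
    the original text.
    """

    model_config = ConfigDict(frozen=True)

    canonical_name: str
    raw_name: str
    value: Union[float, str]
    unit: str = ""
    ref_low: Optional[float] = None
    ref_high: Optional[float] = None
    chart_time: datetime
    source: Literal["laboratory", "microbiology"] = "laboratory"

    @model_validator(mode="after")
    def _ordered_bounds(self) -> "LabResult":
        if self.ref_low is not None and self.ref_high is not None:
            if self.ref_low > self.ref_high:
                raise ValueError(
                    f"ref_low {self.ref_low} > ref_high {self.ref_high} "
                    f"for {self.canonical_name!r}"
                )
        return self

    @property
    def value_num(self) -> Optional[float]:
        if isinstance(self.value, (int, float)):
            return float(self.value)
        try:
            return float(str(self.value).strip())
        except ValueError:
            return None

    def render(self) -> str:
        """One observation line: name, value, unit, reference range."""
        parts = [f"{self.canonical_name}: {self.value}"]
        if self.unit:
            parts.append(self.unit)
        if self.ref_low is not None or self.ref_high is not None:
            lo = "" if self.ref_low is None else f"{self.ref_low:g}"
            hi = "" if self.ref_high is None else f"{self.ref_high:g}"
            parts.append(f"[reference range: {lo} - {hi}]")
        return " ".join(parts)


class RadiologyReport(BaseModel):
    """The findings section of one imaging exam.

    Only descriptive findings are stored; impression/conclusion sections
    carry the radiologist's diagnosis and are discarded upstream.
    """

    model_config = ConfigDict(frozen=True)

    exam_name: str
    modality: Modality
    region: str
    chart_time: datetime
    findings_text: str

    @field_validator("findings_text")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("findings_text must be non-empty")
        return v


class ProcedureRecord(BaseModel):
    """A procedure the patient actually received: an ICD-9/10 procedure
    code, a free-text mention from the discharge summary, or both."""

    model_config = ConfigDict(frozen=True)

    code: Optional[str] = None
    free_text: Optional[str] = None
    source: Literal["coded_table", "discharge_summary"] = "coded_table"

    @model_validator(mode="after")
    def _at_least_one(self) -> "ProcedureRecord":
        if self.code is None and self.free_text is None:
            raise ValueError("ProcedureRecord needs a code or free_text")
        return self


class PatientCase(BaseModel):
    """One admission: gold label plus all servable information.

    Invariants enforced on construction and on load:

    * the history of present illness never mentions the gold pathology
      (mentions are censored to ``___`` during dataset construction, and
      cases where censoring failed are rejected);
    * at least one lab result and one abdominal imaging report exist;
    * the physical examination text is non-empty.
    """

    case_id: str
    pathology: Pathology
    hpi_text: str
    physical_exam_text: str
    labs: list[LabResult]
    reports: list[RadiologyReport]
    procedures: list[ProcedureRecord] = []
    discharge_diagnosis_text: str = ""

    @model_validator(mode="after")
    def _case_invariants(self) -> "PatientCase":
        if contains_pathology_mention(self.hpi_text, self.pathology):
            raise ValueError(
                f"case {self.case_id}: hpi_text mentions the gold pathology; "
                f"censoring invariant ('{CENSOR_MARK}') violated"
            )
        if not self.labs:
            raise ValueError(f"case {self.case_id}: labs must be non-empty")
        if not any(r.region == "abdomen" for r in self.reports):
            raise ValueError(f"case {self.case_id}: no abdominal imaging report")
        if not self.physical_exam_text.strip():
            raise ValueError(f"case {self.case_id}: physical_exam_text empty")
        return self


# --------------------------------------------------------------------------
# Episode transcript types.  ParsedTurn is produced by the environment's
# turn parser (cdm_environment re-exports these).


class ActionKind(str, Enum):
    PHYSICAL_EXAMINATION = "physical_examination"
    LABORATORY_TESTS = "laboratory_tests"
    IMAGING = "imaging"


FormatFlag = Literal[
    "missing_action_field", "free_text_action", "hallucinated_tool", "malformed_final"
]


class ActionOutcome(BaseModel):
    """An information request.  ``kind`` is None when no action could be
    recognized at all (the turn still counts as an action turn and draws a
    corrective observation)."""

    model_config = ConfigDict(frozen=True)

    outcome_type: Literal["action"] = "action"
    kind: Optional[ActionKind] = None
    input_text: str = ""


class FinalOutcome(BaseModel):
    """A terminating diagnosis-and-treatment turn."""

    model_config = ConfigDict(frozen=True)

    outcome_type: Literal["final"] = "final"
    diagnosis_text: str = ""
    treatment_text: Optional[str] = None


class ParsedTurn(BaseModel):
    model_config = ConfigDict(frozen=True)

    thoughts: str = ""
    outcome: Union[ActionOutcome, FinalOutcome]
    format_flags: frozenset[FormatFlag] = frozenset()
    raw_text: str = ""


TerminationReason = Literal["model_diagnosis", "forced_diagnosis"]

ERROR_KEYS = ("next_action_errors", "tool_hallucinations", "diagnosis_format_errors")


class Episode(BaseModel):
    """Full transcript of one agent run over one case."""

    case_id: str
    turns: list[ParsedTurn] = []
    observations: list[str] = []
    requested_labs: list[str] = []
    requested_imaging: list[tuple[str, str]] = []
    physical_exam_requested: bool = False
    physical_exam_first: bool = False
    error_counts: dict[str, int] = {}
    final_diagnosis_text: Optional[str] = None
    treatment_text: Optional[str] = None
    terminated_by: TerminationReason = "model_diagnosis"

    @model_validator(mode="after")
    def _episode_invariants(self) -> "Episode":
        if len(self.observations) > len(self.turns):
            raise ValueError("more observations than turns")
        for key, count in self.error_counts.items():
            if key not in ERROR_KEYS:
                raise ValueError(f"unknown error-count key {key!r}")
            if count < 0:
                raise ValueError(f"negative error count for {key!r}")
        return self


# --------------------------------------------------------------------------
# Line-oriented record store

_HIDDEN_FIELDS = ("pathology", "discharge_diagnosis_text")


def _open(path: Union[str, Path], mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _case_to_record(case: PatientCase) -> dict:
    data = case.model_dump(mode="json")
    hidden = {k: data.pop(k) for k in _HIDDEN_FIELDS}
    data["hidden"] = hidden
    return data


def _case_from_record(data: dict) -> PatientCase:
    data = dict(data)
    hidden = data.pop("hidden", {})
    data.update(hidden)
    return PatientCase.model_validate(data)


def write_cases(cases: Iterable[PatientCase], destination: Union[str, Path]) -> int:
    """Write one JSON record per case; returns the record count.

    Hidden fields (gold pathology, discharge diagnosis) are stored under
    the ``hidden`` key.  Any unserializable case aborts the write naming
    its case_id.
    """
    count = 0
    lines = []
    for case in cases:
        try:
            lines.append(json.dumps(_case_to_record(case), sort_keys=True))
        except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
            raise ValueError(f"cannot serialize case {case.case_id!r}: {exc}") from exc
        count += 1
    with _open(destination, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
    return count


def read_cases(source: Union[str, Path]) -> list[PatientCase]:
    """Load a case store, re-validating every PatientCase invariant."""
    cases = []
    with _open(source, "r") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                cases.append(_case_from_record(json.loads(line)))
            except Exception as exc:
                raise ValueError(f"record {i}: {exc}") from exc
    return cases


def write_episodes(episodes: Iterable[Episode], destination: Union[str, Path]) -> int:
    count = 0
    with _open(destination, "w") as fh:
        for ep in episodes:
            fh.write(json.dumps(ep.model_dump(mode="json"), sort_keys=True) + "\n")
            count += 1
    return count


def read_episodes(source: Union[str, Path]) -> list[Episode]:
    episodes = []
    with _open(source, "r") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                episodes.append(Episode.model_validate(json.loads(line)))
            except Exception as exc:
                raise ValueError(f"record {i}: {exc}") from exc
    return episodes
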