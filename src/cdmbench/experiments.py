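"""Robustness experiment drivers for the full-information task.

Variants perturb exactly one aspect of the assembled prompt — the
instruction phrasing ("final" vs "main"/"primary" diagnosis), removal of
the system instruction or of medical terminology from it, restriction to
a single diagnostic exam, permutation of the information order (history
of present illness always first), an abnormal-labs-only filter, or
disabling the summarization protocol — leaving everything else intact.

:func:`run_matrix` executes the full cases x variants x seeds factorial
with per-cell failure isolation and checkpointing, and aggregates
per-variant per-pathology accuracy means/standard deviations and deltas
against the baseline.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict

from .builder import FIPrompt, build_fi_record
from .environment import (
    STOP_PHRASES,
    Agent,
    FinalOutcome,
    Summarizer,
    TokenBudget,
    first_words_summarizer,
    parse_final_response,
)
from .evaluation import GuidelineSpec, classify_lab_value
from .lexicon import DiagnosisLexicon, match_diagnosis
from .records import LabResult, PatientCase, Pathology

VariantKind = Literal[
    "baseline",
    "instruction_phrasing",
    "remove_system_instructions",
    "remove_medical_terms",
    "single_exam",
    "order_permutation",
    "abnormal_labs_only",
    "no_summarization",
]

#: Content tags a variant may reorder or select; the history of present
#: illness is always included and always first.
CONTENT_TAGS = ("pe", "labs", "imaging")

#: Default substitutions for stripping medical terminology from the
#: system instruction; replaceable via variant parameters.
DEFAULT_TERM_SUBSTITUTIONS: dict[str, str] = {
    "physician": "person",
    "emergency department": "front desk",
    "acute abdominal pain": "a stomach ache",
    "patient": "individual",
    "treatment plan": "plan",
}


class ExperimentVariant(BaseModel):
    model_config = ConfigDict(frozen=True)

    variant_id: str
    kind: VariantKind
    parameters: dict = {}


BASELINE = ExperimentVariant(variant_id="baseline", kind="baseline")


def make_order_permutations() -> list[ExperimentVariant]:
    """All 3! = 6 orderings of physical exam / labs / imaging; the HPI is
    always first.  The canonical (pe, labs, imaging) variant renders
    byte-identically to the baseline."""
    return [
        ExperimentVariant(
            variant_id="order_" + "_".join(order),
            kind="order_permutation",
            parameters={"order": list(order)},
        )
        for order in permutations(CONTENT_TAGS)
    ]


def make_single_exam_variants() -> list[ExperimentVariant]:
    """HPI plus exactly one of physical exam, labs, or imaging."""
    return [
        ExperimentVariant(
            variant_id=f"single_{tag}",
            kind="single_exam",
            parameters={"exam": tag},
        )
        for tag in CONTENT_TAGS
    ]


def make_instruction_variants(
    phrase_set: Sequence[str] = ("main diagnosis", "primary diagnosis"),
    include_removals: bool = True,
) -> list[ExperimentVariant]:
    """One variant per alternative phrasing of "final diagnosis", plus the
    system-instruction removal and medical-terminology removal variants."""
    variants = [
        ExperimentVariant(
            variant_id="phrase_" + phrase.replace(" ", "_"),
            kind="instruction_phrasing",
            parameters={"phrase": phrase},
        )
        for phrase in phrase_set
    ]
    if include_removals:
        variants.append(
            ExperimentVariant(
                variant_id="remove_system_instructions",
                kind="remove_system_instructions",
            )
        )
        variants.append(
            ExperimentVariant(
                variant_id="remove_medical_terms",
                kind="remove_medical_terms",
                parameters={"substitutions": dict(DEFAULT_TERM_SUBSTITUTIONS)},
            )
        )
    return variants


def filter_abnormal_labs(case: PatientCase) -> list[LabResult]:
    """Drop labs classified within their reference range; keep abnormal
    results and results that cannot be judged (non-numeric value or no
    bounds).  Idempotent."""
    return [
        lab
        for lab in case.labs
        if classify_lab_value(lab.value, lab.ref_low, lab.ref_high) != "within"
    ]


def prepare_case(case: PatientCase, variant: ExperimentVariant) -> PatientCase:
    """Case-level variant application (the abnormal-labs filter)."""
    if variant.kind == "abnormal_labs_only":
        return case.model_copy(update={"labs": filter_abnormal_labs(case)})
    return case


def _replace_phrase(text: str, old: str, new: str) -> str:
    def repl(m: re.Match) -> str:
        return new.title() if m.group(0)[0].isupper() else new

    return re.sub(re.escape(old), repl, text, flags=re.IGNORECASE)


def apply_variant(fi: FIPrompt, variant: ExperimentVariant) -> FIPrompt:
    """Prompt-level variant application; returns a new FIPrompt whose
    content differs from the input only in what the variant's kind names."""
    instructions = fi.instructions
    spans = list(fi.spans)
    kind = variant.kind
    if kind in ("baseline", "abnormal_labs_only", "no_summarization"):
        pass
    elif kind == "instruction_phrasing":
        instructions = _replace_phrase(
            instructions, "final diagnosis", variant.parameters["phrase"]
        )
    elif kind == "remove_system_instructions":
        instructions = ""
    elif kind == "remove_medical_terms":
        subs = variant.parameters.get("substitutions", DEFAULT_TERM_SUBSTITUTIONS)
        for term, repl in subs.items():
            instructions = _replace_phrase(instructions, term, repl)
    elif kind == "single_exam":
        keep = variant.parameters["exam"]
        spans = [s for s in spans if s[0] == "hpi" or s[0] == keep]
    elif kind == "order_permutation":
        order = variant.parameters["order"]
        head = [s for s in spans if s[0] not in CONTENT_TAGS]
        spans = head + [s for tag in order for s in spans if s[0] == tag]
    else:  # pragma: no cover - closed enum
        raise ValueError(f"unknown variant kind {kind!r}")
    return FIPrompt(instructions=instructions, spans=spans)


def make_fi_prompt(
    case: PatientCase,
    variant: ExperimentVariant,
    guideline: GuidelineSpec,
    budget: Optional[TokenBudget] = None,
    summarizer: Optional[Summarizer] = None,
) -> FIPrompt:
    """Assemble the (possibly perturbed) full-information prompt for one
    case under one variant."""
    if variant.kind == "no_summarization":
        def summarizer(_text: str) -> str:  # noqa: F811 - deliberate disable
            raise RuntimeError("summarization disabled by variant")

    prepared = prepare_case(case, variant)
    fi = build_fi_record(prepared, guideline, budget, summarizer)
    return apply_variant(fi, variant)


# --------------------------------------------------------------------------
# Run matrix


@dataclass(frozen=True)
class RunRecord:
    case_id: str
    pathology: str
    variant_id: str
    seed: int
    diagnosis_text: str
    correct: bool
    failed: bool = False


@dataclass
class RunMatrix:
    """Cases x variants x seeds factorial results."""

    records: list[RunRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def aggregate(self) -> pd.DataFrame:
        """Per-variant per-pathology accuracy mean and standard deviation
        over seeds (failed cells count as incorrect)."""
        df = self.to_frame()
        per_seed = (
            df.groupby(["variant_id", "pathology", "seed"])["correct"]
            .mean()
            .mul(100.0)
            .reset_index(name="accuracy")
        )
        agg = (
            per_seed.groupby(["variant_id", "pathology"])["accuracy"]
            .agg(mean="mean", sd="std", n="count")
            .reset_index()
        )
        agg["sd"] = agg["sd"].fillna(0.0)
        return agg

    def deltas_vs_baseline(self, baseline_id: str = "baseline") -> pd.DataFrame:
        agg = self.aggregate()
        base = agg[agg["variant_id"] == baseline_id].set_index("pathology")["mean"]
        out = agg[agg["variant_id"] != baseline_id].copy()
        out["delta"] = out.apply(
            lambda r: r["mean"] - base.get(r["pathology"], float("nan")), axis=1
        )
        return out


AgentFactory = Callable[[int], Agent]


def run_matrix(
    cases: Sequence[PatientCase],
    make_agent: AgentFactory,
    variants: Sequence[ExperimentVariant],
    seeds: Sequence[int],
    guideline: Optional[GuidelineSpec] = None,
    diagnosis_lexicon: Optional[DiagnosisLexicon] = None,
    budget: Optional[TokenBudget] = None,
    checkpoint_path: Optional[Union[str, Path]] = None,
) -> RunMatrix:
    """Full factorial execution of the FI task.

    ``make_agent(seed)`` must return a fresh agent per cell (scripted
    agents are stateful); deterministic agents simply ignore the seed.
    A failing cell is recorded as failed (and incorrect) without aborting
    the matrix.  With ``checkpoint_path``, completed cells are appended to
    a JSONL file and skipped on re-run.
    """
    guideline = guideline or GuidelineSpec.from_yaml()
    diagnosis_lexicon = diagnosis_lexicon or DiagnosisLexicon.from_yaml()
    matrix = RunMatrix()
    done: set[tuple[str, str, int]] = set()
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        for line in Path(checkpoint_path).read_text().splitlines():
            rec = RunRecord(**json.loads(line))
            matrix.records.append(rec)
            done.add((rec.case_id, rec.variant_id, rec.seed))
    for case in cases:
        for variant in variants:
            for seed in seeds:
                key = (case.case_id, variant.variant_id, seed)
                if key in done:
                    continue
                try:
                    fi = make_fi_prompt(case, variant, guideline, budget)
                    agent = make_agent(seed)
                    if hasattr(agent, "set_seed"):
                        agent.set_seed(seed)
                    raw = agent(fi.render(), stop=STOP_PHRASES)
                    turn = parse_final_response(raw)
                    assert isinstance(turn.outcome, FinalOutcome)
                    diagnosis = turn.outcome.diagnosis_text
                    rec = RunRecord(
                        case_id=case.case_id,
                        pathology=case.pathology.value,
                        variant_id=variant.variant_id,
                        seed=seed,
                        diagnosis_text=diagnosis,
                        correct=match_diagnosis(
                            diagnosis, case.pathology, diagnosis_lexicon
                        ),
                    )
                except Exception:
                    rec = RunRecord(
                        case_id=case.case_id,
                        pathology=case.pathology.value,
                        variant_id=variant.variant_id,
                        seed=seed,
                        diagnosis_text="",
                        correct=False,
                        failed=True,
                    )
                matrix.records.append(rec)
                if checkpoint_path is not None:
                    with open(checkpoint_path, "a", encoding="utf-8") as fh:
                        fh.write(json.dumps(rec.__dict__) + "\n")
    return matrix
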