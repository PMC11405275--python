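"""The interactive clinical decision-making loop.

The environment presents an agent with task instructions and a patient's
history of present illness, then alternates agent turns and served
observations: the agent states its thoughts and either requests more
information (physical examination, laboratory tests or imaging) or
provides a final diagnosis and treatment plan.

Deviations from the requested format never fail an episode — the
environment still serves the appropriate information where it can — but
every deviation is tallied (next-action errors, tool hallucinations,
diagnosis format errors).

A pluggable token budget models the agent's context limit.  When the
conversation approaches the limit, gathered observations are summarized
one at a time (instructions and the history of present illness are never
touched); once everything is summarized and the limit is still near, the
environment forces a diagnosis.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence, Union

from .lexicon import (
    AmbiguousRequestError,
    ImagingLexicon,
    LabLexicon,
    classify_imaging_request,
    match_lab_request,
    normalize,
)
from .records import (
    ActionKind,
    ActionOutcome,
    Episode,
    FinalOutcome,
    Modality,
    ParsedTurn,
    PatientCase,
)

# Generation is truncated at the first of these phrases: past this point a
# model would start hallucinating the result of its own request.
STOP_PHRASES: tuple[str, ...] = ("Observation:", "Observations:")

_OBS_MARKER_RE = re.compile(r"(?i)\bobservations?\s*:")

EXHAUSTED_MESSAGE = (
    "We can no longer provide reports of that modality and region combination. "
    "Please request a different action."
)
UNCLASSIFIABLE_IMAGING_MESSAGE = (
    "The requested imaging exam could not be identified. Please specify a "
    "modality (CT, Ultrasound, MRI, Radiograph) and an anatomical region, "
    "or choose an alternative action."
)
MISSING_ACTION_MESSAGE = (
    'Please state "Action:" followed by Physical Examination, Laboratory '
    'Tests, or Imaging, with an "Action Input:", or provide a Final '
    "Diagnosis and Treatment plan."
)


def hallucinated_tool_message(tool_name: str) -> str:
    return (
        f'The tool "{tool_name}" does not exist. Available tools are: '
        "Physical Examination, Laboratory Tests, and Imaging. Alternatively, "
        "provide a Final Diagnosis and Treatment plan."
    )


# --------------------------------------------------------------------------
# Token budget


def word_token_counter(text: str) -> int:
    """Default counter: word count x 1.71 (the 4,096-token ~ 2,400-word
    context ratio), rounded up.  Replaceable with a real tokenizer."""
    return math.ceil(len(text.split()) * 1.71)


@dataclass(frozen=True)
class TokenBudget:
    """Context-window model: a hard token limit, a pluggable text->count
    function, and a reserve so a diagnosis (25 tokens / 20 words) always
    fits."""

    limit: int = 4096
    counter: Callable[[str], int] = word_token_counter
    reserve_tokens: int = 25
    reserve_words: int = 20
    # "approaching the limit" threshold as a fraction of the limit
    threshold_frac: float = 0.9

    def __post_init__(self) -> None:
        if self.limit <= self.reserve_tokens:
            raise ValueError("budget limit must exceed the diagnosis reserve")

    @property
    def threshold(self) -> int:
        return int(self.limit * self.threshold_frac)

    @property
    def usable(self) -> int:
        return self.limit - self.reserve_tokens

    def count(self, text: str) -> int:
        return self.counter(text)


Summarizer = Callable[[str], str]


def first_words_summarizer(k: int = 30) -> Summarizer:
    """Trivial deterministic summarizer: the first *k* words."""

    def summarize(text: str) -> str:
        return " ".join(text.split()[:k])

    return summarize


# --------------------------------------------------------------------------
# Turn parsing

_FINAL_DX_RE = re.compile(
    r"(?i)\b(?:final|main|primary)\s+diagnosis\s*:\s*(.*?)(?=\btreatment(?:\s+plan)?\s*:|\Z)",
    re.DOTALL,
)
_TREATMENT_RE = re.compile(r"(?i)\btreatment(?:\s+plan)?\s*:\s*(.*)", re.DOTALL)
_ACTION_RE = re.compile(r"(?i)\baction\s*:\s*([^\n]+)")
_ACTION_INPUT_RE = re.compile(r"(?i)\baction\s+input\s*:\s*(.*)", re.DOTALL)
_THOUGHTS_RE = re.compile(
    r"(?i)\bthoughts?\s*:\s*(.*?)(?=\baction\s*:|\b(?:final|main|primary)\s+diagnosis\s*:|\Z)",
    re.DOTALL,
)

_TOOL_KEYWORDS: tuple[tuple[str, ActionKind], ...] = (
    ("physical examination", ActionKind.PHYSICAL_EXAMINATION),
    ("physical exam", ActionKind.PHYSICAL_EXAMINATION),
    ("laboratory tests", ActionKind.LABORATORY_TESTS),
    ("laboratory test", ActionKind.LABORATORY_TESTS),
    ("lab tests", ActionKind.LABORATORY_TESTS),
    ("lab test", ActionKind.LABORATORY_TESTS),
    ("laboratory", ActionKind.LABORATORY_TESTS),
    ("labs", ActionKind.LABORATORY_TESTS),
    ("imaging", ActionKind.IMAGING),
)


def truncate_at_observation(raw_text: str) -> str:
    """Cut the response at the first occurrence of the observation marker."""
    m = _OBS_MARKER_RE.search(raw_text)
    return raw_text[: m.start()] if m else raw_text


def _classify_tool_name(name: str) -> Optional[ActionKind]:
    n = normalize(name)
    for kw, kind in _TOOL_KEYWORDS:
        if kw in n:
            return kind
    return None


def parse_turn(raw_text: str, require_treatment: bool = True) -> ParsedTurn:
    """Parse one agent response into thoughts + an action or final turn.

    Tolerant by design: responses that skip the labeled-field grammar but
    name a tool in prose are still understood (``free_text_action``); a
    named tool outside the closed set is ``hallucinated_tool``; a final
    turn lacking required fields is ``malformed_final``.  Deviations are
    flags, never failures.
    """
    text = truncate_at_observation(raw_text)
    flags: set[str] = set()
    thoughts_m = _THOUGHTS_RE.search(text)
    thoughts = thoughts_m.group(1).strip() if thoughts_m else ""

    final_m = _FINAL_DX_RE.search(text)
    if final_m:
        diagnosis = final_m.group(1).strip()
        treat_m = _TREATMENT_RE.search(text)
        treatment = treat_m.group(1).strip() if treat_m else None
        if not diagnosis or (require_treatment and not treatment):
            flags.add("malformed_final")
        return ParsedTurn(
            thoughts=thoughts,
            outcome=FinalOutcome(diagnosis_text=diagnosis, treatment_text=treatment),
            format_flags=frozenset(flags),
            raw_text=text,
        )

    action_m = _ACTION_RE.search(text)
    input_m = _ACTION_INPUT_RE.search(text)
    input_text = input_m.group(1).strip() if input_m else ""
    if action_m:
        tool_name = action_m.group(1).strip()
        kind = _classify_tool_name(tool_name)
        if kind is None:
            flags.add("hallucinated_tool")
            input_text = input_text or tool_name
        return ParsedTurn(
            thoughts=thoughts,
            outcome=ActionOutcome(kind=kind, input_text=input_text),
            format_flags=frozenset(flags),
            raw_text=text,
        )

    # no labeled Action field: look for a tool named in prose
    n = normalize(text)
    best: Optional[tuple[int, ActionKind]] = None
    for kw, kind in _TOOL_KEYWORDS:
        pos = n.find(kw)
        if pos >= 0 and (best is None or pos < best[0]):
            best = (pos, kind)
    if best is not None:
        flags.add("free_text_action")
        return ParsedTurn(
            thoughts=thoughts,
            outcome=ActionOutcome(kind=best[1], input_text=input_text or text.strip()),
            format_flags=frozenset(flags),
            raw_text=text,
        )

    flags.add("missing_action_field")
    return ParsedTurn(
        thoughts=thoughts,
        outcome=ActionOutcome(kind=None, input_text=text.strip()),
        format_flags=frozenset(flags),
        raw_text=text,
    )


def parse_final_response(raw_text: str) -> ParsedTurn:
    """Parse a (possibly forced) diagnosis response; anything without the
    labeled fields is kept verbatim as the diagnosis text and flagged."""
    text = truncate_at_observation(raw_text)
    turn = parse_turn(raw_text)
    if isinstance(turn.outcome, FinalOutcome):
        return turn
    return ParsedTurn(
        thoughts=turn.thoughts,
        outcome=FinalOutcome(diagnosis_text=text.strip(), treatment_text=None),
        format_flags=frozenset({"malformed_final"}),
        raw_text=text,
    )


# --------------------------------------------------------------------------
# Environment state and observation serving


@dataclass
class Span:
    tag: str  # instructions | hpi | turn | observation | request
    text: str
    summarized: bool = False


@dataclass
class EnvironmentState:
    case: PatientCase
    conversation: list[Span]
    imaging_cursor: dict[tuple[str, str], int] = field(default_factory=dict)
    served_pe: bool = False
    summarization_stage: str = "none"  # none | per_item | all_summarized

    def render(self) -> str:
        return "\n\n".join(s.text for s in self.conversation)


def _sorted_reports(case: PatientCase, modality: Modality, region: str):
    reports = [
        r for r in case.reports if r.modality == modality and r.region == region
    ]
    return sorted(enumerate(reports), key=lambda ir: (ir[1].chart_time, ir[0]))


def serve_observation(
    state: EnvironmentState,
    turn: ParsedTurn,
    lab_lexicon: LabLexicon,
    imaging_lexicon: ImagingLexicon,
) -> str:
    """Serve the observation for an action turn, updating the state.

    Physical examination returns the entire exam text regardless of the
    action input.  Lab requests are matched against the synonym
    dictionary; unmatched or unavailable tests render "NA".  Imaging
    requests walk the case's reports for the requested (modality, region)
    in chart order, one report per request, until exhausted.
    """
    outcome = turn.outcome
    assert isinstance(outcome, ActionOutcome)
    case = state.case

    if "hallucinated_tool" in turn.format_flags:
        return hallucinated_tool_message(outcome.input_text or "requested tool")
    if outcome.kind is None:
        return MISSING_ACTION_MESSAGE

    if outcome.kind is ActionKind.PHYSICAL_EXAMINATION:
        state.served_pe = True
        return f"Physical Examination:\n{case.physical_exam_text}"

    if outcome.kind is ActionKind.LABORATORY_TESTS:
        names = match_lab_request(outcome.input_text, lab_lexicon)
        if not names:
            return "NA"
        by_name = {}
        for lab in case.labs:
            by_name.setdefault(lab.canonical_name, lab)
        lines = []
        for name in names:
            lab = by_name.get(name)
            lines.append(lab.render() if lab is not None else f"{name}: NA")
        return "\n".join(lines)

    # imaging
    try:
        classified = classify_imaging_request(outcome.input_text, imaging_lexicon)
    except AmbiguousRequestError:
        classified = None
    if classified is None:
        return UNCLASSIFIABLE_IMAGING_MESSAGE
    modality, region = classified
    key = (modality.value, region)
    idx = state.imaging_cursor.get(key, 0)
    reports = _sorted_reports(case, modality, region)
    if idx >= len(reports):
        return EXHAUSTED_MESSAGE
    state.imaging_cursor[key] = idx + 1
    report = reports[idx][1]
    return f"{report.exam_name} findings:\n{report.findings_text}"


# --------------------------------------------------------------------------
# Summarization under the budget


def _load_template(name: str) -> str:
    return (
        resources.files("cdmbench")
        .joinpath("data", "templates", name)
        .read_text(encoding="utf-8")
    )


def maybe_summarize(
    state: EnvironmentState, budget: TokenBudget, summarizer: Summarizer
) -> bool:
    """Summarize gathered information if the conversation approaches the
    budget; returns True when a forced diagnosis must be triggered.

    Observation spans are summarized individually, oldest first; the
    instructions and history of present illness are never touched.  If
    every observation has been summarized and the conversation still
    approaches the limit, the episode must end with a forced diagnosis.
    """
    if budget.count(state.render()) <= budget.threshold:
        return False
    for span in state.conversation:
        if span.tag == "observation" and not span.summarized:
            try:
                span.text = summarizer(span.text)
            except Exception:
                state.summarization_stage = "all_summarized"
                return True
            span.summarized = True
            state.summarization_stage = "per_item"
            if budget.count(state.render()) <= budget.threshold:
                return False
    if any(s.tag == "observation" for s in state.conversation):
        state.summarization_stage = "all_summarized"
    return budget.count(state.render()) > budget.threshold


def _enforce_budget(state: EnvironmentState, budget: TokenBudget) -> None:
    """Hard guard: trim words off the newest summarizable spans until the
    prompt fits in limit - reserve; instructions/HPI are never trimmed."""
    while budget.count(state.render()) > budget.usable:
        trimmed = False
        for span in reversed(state.conversation):
            if span.tag in ("instructions", "hpi"):
                continue
            words = span.text.split()
            if words:
                span.text = " ".join(words[:-1])
                trimmed = True
                break
        if not trimmed:
            break


# --------------------------------------------------------------------------
# Episode driver


class Agent(Protocol):
    def __call__(self, prompt: str, stop: Sequence[str] = ()) -> str: ...


@dataclass
class EnvConfig:
    lab_lexicon: LabLexicon
    imaging_lexicon: ImagingLexicon
    budget: TokenBudget = field(default_factory=TokenBudget)
    max_turns: int = 15
    summarizer: Optional[Summarizer] = None
    instructions: Optional[str] = None
    forced_diagnosis_request: Optional[str] = None

    def resolved_instructions(self) -> str:
        return self.instructions or _load_template("cdm_instructions.txt")

    def resolved_forced_request(self) -> str:
        return self.forced_diagnosis_request or _load_template("forced_diagnosis.txt")


def _resolve_summarizer(agent, config: EnvConfig) -> Summarizer:
    if config.summarizer is not None:
        return config.summarizer
    if hasattr(agent, "summarize"):
        return agent.summarize
    return first_words_summarizer()


def run_episode(case: PatientCase, agent: Agent, config: EnvConfig) -> Episode:
    """Run the full interactive clinical decision-making task on one case.

    The loop is prompt -> agent -> parse -> serve observation, repeated
    until the agent issues a final diagnosis, the context budget forces
    one, or the turn cap is hit (which also forces one).  No state leaks
    across cases: each call builds a fresh environment.
    """
    summarizer = _resolve_summarizer(agent, config)
    state = EnvironmentState(
        case=case,
        conversation=[
            Span("instructions", config.resolved_instructions()),
            Span("hpi", f"History of Present Illness:\n{case.hpi_text}"),
        ],
    )
    errors = {
        "next_action_errors": 0,
        "tool_hallucinations": 0,
        "diagnosis_format_errors": 0,
    }
    turns: list[ParsedTurn] = []
    observations: list[str] = []
    requested_labs: list[str] = []
    requested_imaging: list[tuple[str, str]] = []
    pe_requested = False
    pe_first = False
    first_action_seen = False
    final_turn: Optional[ParsedTurn] = None
    terminated_by = "model_diagnosis"

    for _ in range(config.max_turns):
        force = maybe_summarize(state, config.budget, summarizer)
        if force:
            terminated_by = "forced_diagnosis"
            break
        _enforce_budget(state, config.budget)
        raw = agent(state.render(), stop=STOP_PHRASES)
        turn = parse_turn(raw)
        turns.append(turn)
        if "missing_action_field" in turn.format_flags or "free_text_action" in turn.format_flags:
            errors["next_action_errors"] += 1
        if "hallucinated_tool" in turn.format_flags:
            errors["tool_hallucinations"] += 1
        if isinstance(turn.outcome, FinalOutcome):
            if "malformed_final" in turn.format_flags:
                errors["diagnosis_format_errors"] += 1
            final_turn = turn
            break
        # action turn
        if not first_action_seen:
            first_action_seen = True
            pe_first = turn.outcome.kind is ActionKind.PHYSICAL_EXAMINATION
        if turn.outcome.kind is ActionKind.PHYSICAL_EXAMINATION:
            pe_requested = True
        if turn.outcome.kind is ActionKind.LABORATORY_TESTS:
            requested_labs.extend(
                n
                for n in match_lab_request(turn.outcome.input_text, config.lab_lexicon)
                if n not in requested_labs
            )
        if turn.outcome.kind is ActionKind.IMAGING:
            try:
                classified = classify_imaging_request(
                    turn.outcome.input_text, config.imaging_lexicon
                )
            except AmbiguousRequestError:
                classified = None
            if classified is not None:
                requested_imaging.append((classified[0].value, classified[1]))
        obs = serve_observation(state, turn, config.lab_lexicon, config.imaging_lexicon)
        observations.append(obs)
        state.conversation.append(Span("turn", turn.raw_text))
        state.conversation.append(Span("observation", obs))
    else:
        terminated_by = "forced_diagnosis"

    if final_turn is None:
        # forced diagnosis: one last agent call with the forced request
        state.conversation.append(Span("request", config.resolved_forced_request()))
        _enforce_budget(state, config.budget)
        raw = agent(state.render(), stop=STOP_PHRASES)
        final_turn = parse_final_response(raw)
        turns.append(final_turn)
        if "malformed_final" in final_turn.format_flags:
            errors["diagnosis_format_errors"] += 1
        terminated_by = "forced_diagnosis"

    assert isinstance(final_turn.outcome, FinalOutcome)
    return Episode(
        case_id=case.case_id,
        turns=turns,
        observations=observations,
        requested_labs=requested_labs,
        requested_imaging=requested_imaging,
        physical_exam_requested=pe_requested,
        physical_exam_first=pe_first,
        error_counts=errors,
        final_diagnosis_text=final_turn.outcome.diagnosis_text,
        treatment_text=final_turn.outcome.treatment_text,
        terminated_by=terminated_by,
    )


def run_fi(
    case: PatientCase,
    agent: Agent,
    config: EnvConfig,
    guideline=None,
    variant=None,
) -> str:
    """Single-shot full-information task: one assembled prompt, one
    response, the diagnosis text extracted from it."""
    from .builder import build_fi_record
    from .experiments import BASELINE, make_fi_prompt

    summarizer = _resolve_summarizer(agent, config)
    if guideline is None:
        from .evaluation import GuidelineSpec

        guideline = GuidelineSpec.from_yaml()
    if variant is None:
        fi = build_fi_record(case, guideline, config.budget, summarizer)
    else:
        fi = make_fi_prompt(case, variant, guideline, config.budget, summarizer)
    raw = agent(fi.render(), stop=STOP_PHRASES)
    turn = parse_final_response(raw)
    assert isinstance(turn.outcome, FinalOutcome)
    return turn.outcome.diagnosis_text
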