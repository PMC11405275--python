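"""Scoring of episodes and full-information runs.

Covers diagnostic accuracy (per-class only: correct diagnoses over all
patients of one pathology), diagnostic-guideline adherence (required lab
test categories, physical-examination ordering, imaging requests —
recorded but never penalized), treatment appropriateness (essential
treatments always expected; case-specific treatments only for patients
who actually received the matching procedure; treatment is scored only on
correctly diagnosed cases), laboratory-value interpretation, and the
statistical comparisons (Welch two-sided t-tests with Bonferroni
correction).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .lexicon import DiagnosisLexicon, match_diagnosis, normalize
from .records import Episode, LabResult, PatientCase, Pathology, ProcedureRecord

TreatmentFlag = Literal["recommended", "missed", "not_applicable"]

#: The composite supportive-care treatment (fluids / pain management /
#: monitoring); "any" mode needs one mention, "all" mode needs all three.
SUPPORT = "support"


@dataclass(frozen=True)
class ProcedurePredicate:
    keywords: tuple[str, ...]
    code_prefixes: tuple[str, ...] = ()

    def matches(self, procedures: Sequence[ProcedureRecord]) -> bool:
        for proc in procedures:
            if proc.free_text:
                text = normalize(proc.free_text)
                if any(kw in text for kw in self.keywords):
                    return True
            if proc.code:
                code = proc.code.replace(".", "").upper()
                if any(code.startswith(p.replace(".", "").upper()) for p in self.code_prefixes):
                    return True
        return False


@dataclass(frozen=True)
class PathologyGuideline:
    lab_categories: dict[str, tuple[str, ...]]
    essential_treatments: tuple[str, ...]
    case_specific_treatments: dict[str, ProcedurePredicate]
    support_mode: Literal["any", "all"]

    def __post_init__(self) -> None:
        for cat, members in self.lab_categories.items():
            if not members:
                raise ValueError(f"lab category {cat!r} is empty")


@dataclass(frozen=True)
class GuidelineSpec:
    """Per-pathology diagnostic and treatment guideline rules, plus the
    surface keywords used to recognize treatment mentions."""

    pathologies: dict[Pathology, PathologyGuideline]
    treatment_keywords: dict[str, tuple[str, ...]]
    support_keywords: dict[str, tuple[str, ...]]

    @classmethod
    def from_config(cls, config: dict) -> "GuidelineSpec":
        pathologies = {}
        for name, spec in config["pathologies"].items():
            pathologies[Pathology(name)] = PathologyGuideline(
                lab_categories={
                    cat: tuple(members)
                    for cat, members in spec["lab_categories"].items()
                },
                essential_treatments=tuple(spec.get("essential_treatments", [])),
                case_specific_treatments={
                    t: ProcedurePredicate(
                        keywords=tuple(normalize(k) for k in p.get("procedure_keywords", [])),
                        code_prefixes=tuple(p.get("procedure_codes", [])),
                    )
                    for t, p in spec.get("case_specific_treatments", {}).items()
                },
                support_mode=spec.get("support_mode", "any"),
            )
        return cls(
            pathologies=pathologies,
            treatment_keywords={
                t: tuple(normalize(k) for k in kws)
                for t, kws in config.get("treatment_keywords", {}).items()
            },
            support_keywords={
                t: tuple(normalize(k) for k in kws)
                for t, kws in config.get("support_keywords", {}).items()
            },
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None) -> "GuidelineSpec":
        if path is None:
            path = Path(str(resources.files("cdmbench").joinpath("data", "guidelines.yaml")))
        return cls.from_config(yaml.safe_load(Path(path).read_text()))

    def all_relevant_tests(self) -> tuple[str, ...]:
        """Union of every pathology's category members: the labs relevant
        for the diagnosis and for ruling out the differentials."""
        out: dict[str, None] = {}
        for pg in self.pathologies.values():
            for members in pg.lab_categories.values():
                for m in members:
                    out.setdefault(m)
        return tuple(out)


@dataclass
class CaseScore:
    case_id: str
    pathology: Pathology
    diagnosed_correctly: bool
    pe_first: bool
    pe_at_all: bool
    lab_categories_met: dict[str, bool]
    imaging_requested: list[tuple[str, str]]
    treatment_flags: dict[str, TreatmentFlag]
    error_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.diagnosed_correctly and self.treatment_flags:
            raise ValueError("treatment scored despite incorrect diagnosis")


# --------------------------------------------------------------------------
# Treatment-text matching

_NEGATION_RE = re.compile(r"\b(?:no|not|without|avoid|hold)\b(?:\s+\w+){0,3}\s*$")


def _mentions(text_norm: str, keywords: Sequence[str]) -> bool:
    """Keyword containment with a small negation guard: a keyword preceded
    within a few words by no/not/without/avoid does not count."""
    for kw in keywords:
        for m in re.finditer(re.escape(kw), text_norm):
            prefix = text_norm[: m.start()]
            if not _NEGATION_RE.search(prefix):
                return True
    return False


def _support_met(text_norm: str, guideline: GuidelineSpec, mode: str) -> bool:
    hits = [
        _mentions(text_norm, kws) for kws in guideline.support_keywords.values()
    ]
    return all(hits) if mode == "all" else any(hits)


def score_treatment_text(
    treatment_text: str,
    pathology: Pathology,
    guideline: GuidelineSpec,
    received: Sequence[ProcedureRecord],
) -> dict[str, TreatmentFlag]:
    """Score a treatment plan against the guideline for *pathology*.

    Essential treatments are always expected.  Case-specific treatments
    are evaluated only when the patient actually received the matching
    procedure; otherwise they are ``not_applicable``.
    """
    pg = guideline.pathologies[pathology]
    text_norm = normalize(treatment_text)
    flags: dict[str, TreatmentFlag] = {}
    for treatment in pg.essential_treatments:
        if treatment == SUPPORT:
            met = _support_met(text_norm, guideline, pg.support_mode)
        else:
            met = _mentions(text_norm, guideline.treatment_keywords[treatment])
        flags[treatment] = "recommended" if met else "missed"
    for treatment, predicate in pg.case_specific_treatments.items():
        if not predicate.matches(received):
            flags[treatment] = "not_applicable"
        elif _mentions(text_norm, guideline.treatment_keywords[treatment]):
            flags[treatment] = "recommended"
        else:
            flags[treatment] = "missed"
    return flags


def score_episode(
    episode: Episode,
    case: PatientCase,
    guideline: GuidelineSpec,
    diagnosis_lexicon: DiagnosisLexicon,
) -> CaseScore:
    """Score one completed episode against its case.

    A required lab category is met iff at least one member test was
    requested.  Treatment is scored only when the diagnosis was correct,
    since an inaccurate diagnosis likely leads to inappropriate treatment.
    Imaging requests are recorded but not penalized.
    """
    if case.pathology not in guideline.pathologies:
        raise ValueError(f"no guideline configured for {case.pathology}")
    pg = guideline.pathologies[case.pathology]
    diagnosed = match_diagnosis(
        episode.final_diagnosis_text or "", case.pathology, diagnosis_lexicon
    )
    categories = {
        cat: any(test in episode.requested_labs for test in members)
        for cat, members in pg.lab_categories.items()
    }
    treatment_flags: dict[str, TreatmentFlag] = {}
    if diagnosed:
        treatment_flags = score_treatment_text(
            episode.treatment_text or "", case.pathology, guideline, case.procedures
        )
    return CaseScore(
        case_id=case.case_id,
        pathology=case.pathology,
        diagnosed_correctly=diagnosed,
        pe_first=episode.physical_exam_first,
        pe_at_all=episode.physical_exam_requested,
        lab_categories_met=categories,
        imaging_requested=list(episode.requested_imaging),
        treatment_flags=treatment_flags,
        error_counts=dict(episode.error_counts),
    )


# --------------------------------------------------------------------------
# Laboratory interpretation

InterpretationLabel = Literal["below", "within", "above"]


def classify_lab_value(
    value: Union[float, str],
    ref_low: Optional[float],
    ref_high: Optional[float],
) -> Optional[InterpretationLabel]:
    """Classify a result as below/within/above its reference range.

    Bounds are inclusive: a value equal to either bound is within.  A
    missing low bound can never yield "below", a missing high bound never
    "above".  Non-numeric values (or no bounds at all) are not
    classifiable and return None.
    """
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None
    if ref_low is None and ref_high is None:
        return None
    if ref_low is not None and v < ref_low:
        return "below"
    if ref_high is not None and v > ref_high:
        return "above"
    return "within"


def score_interpretations(
    model_labels: Sequence[str], gold_items: Sequence
) -> dict[str, float]:
    """Per-label accuracy (percent) of predicted range classifications.

    ``gold_items`` may be InterpretationItem-like objects (with a
    ``gold_label`` attribute) or plain label strings.
    """
    if len(model_labels) != len(gold_items):
        raise ValueError("model labels and gold items are not aligned")
    golds = [getattr(g, "gold_label", g) for g in gold_items]
    out: dict[str, float] = {}
    for label in ("below", "within", "above"):
        idx = [i for i, g in enumerate(golds) if g == label]
        if not idx:
            continue
        correct = sum(1 for i in idx if model_labels[i] == label)
        out[label] = 100.0 * correct / len(idx)
    return out


# --------------------------------------------------------------------------
# Aggregate metrics and statistics


def per_class_accuracy(scores: Sequence[CaseScore], pathology: Pathology) -> float:
    """Percent of correctly diagnosed cases among all cases of one
    pathology; never pooled across classes."""
    relevant = [s for s in scores if s.pathology == pathology]
    if not relevant:
        raise ValueError(f"no cases of {pathology}")
    return 100.0 * sum(s.diagnosed_correctly for s in relevant) / len(relevant)


def compare_groups(
    a: Sequence[float], b: Sequence[float], n_comparisons: int = 1
) -> float:
    """Welch two-sided t-test between two accuracy samples, Bonferroni
    corrected: p_corr = min(1, p x n_comparisons)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return min(1.0, p * n_comparisons)


def aggregate_scores(scores: Sequence[CaseScore]) -> pd.DataFrame:
    """Tidy per-pathology summary: diagnostic accuracy, PE ordering rates,
    lab-category adherence, and treatment recommendation rates (on the
    correctly diagnosed subset with the treatment applicable)."""
    rows = []
    for pathology in Pathology:
        subset = [s for s in scores if s.pathology == pathology]
        if not subset:
            continue
        n = len(subset)
        row: dict[str, object] = {
            "pathology": pathology.value,
            "n": n,
            "diagnostic_accuracy": per_class_accuracy(subset, pathology),
            "pe_first_pct": 100.0 * sum(s.pe_first for s in subset) / n,
            "pe_at_all_pct": 100.0 * sum(s.pe_at_all for s in subset) / n,
        }
        cats: dict[str, list[bool]] = {}
        for s in subset:
            for cat, met in s.lab_categories_met.items():
                cats.setdefault(cat, []).append(met)
        for cat, vals in cats.items():
            row[f"category_{cat}_pct"] = 100.0 * sum(vals) / len(vals)
        treatments: dict[str, list[bool]] = {}
        for s in subset:
            for t, flag in s.treatment_flags.items():
                if flag != "not_applicable":
                    treatments.setdefault(t, []).append(flag == "recommended")
        for t, vals in treatments.items():
            row[f"treatment_{t}_pct"] = 100.0 * sum(vals) / len(vals)
        rows.append(row)
    return pd.DataFrame(rows)
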