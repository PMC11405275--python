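"""Dictionaries and matchers for free-text clinical requests.

Three lexicons translate agent text into the environment's closed
vocabularies:

* :class:`LabLexicon` — synonyms/abbreviations of laboratory tests and
  panel names (CBC, BMP, liver function panel, ...) mapped to canonical
  test names;
* :class:`ImagingLexicon` — uniquely identifying keywords for imaging
  modalities and anatomical regions, plus special-exam mappings such as
  MRCP -> (MRI, abdomen);
* :class:`DiagnosisLexicon` — per-pathology accepted alternative
  phrasings for diagnosis matching.

All content ships as human-editable YAML and is an explicitly replaceable
reconstruction of standard clinical vocabulary.

Matching is normalization-then-exact, then longest-alias-substring; an
unmatched lab request is an empty result (the environment renders "NA"),
never an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .records import Modality, Pathology

_WORD_RE = re.compile(r"[a-z0-9]+")


def normalize(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_WORD_RE.findall(text.lower()))


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cdmbench").joinpath("data", name)))


# --------------------------------------------------------------------------
# Laboratory tests


@dataclass(frozen=True)
class LabLexicon:
    synonym_map: dict[str, str]  # normalized alias -> canonical name
    panel_map: dict[str, tuple[str, ...]]  # normalized panel name -> members

    def __post_init__(self) -> None:
        canon = set(self.synonym_map.values())
        for panel, members in self.panel_map.items():
            for m in members:
                if m not in canon:
                    raise ValueError(
                        f"panel {panel!r} member {m!r} is not a canonical test"
                    )

    @property
    def canonical_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.synonym_map.values():
            seen.setdefault(c)
        return tuple(seen)

    @classmethod
    def from_config(cls, config: dict) -> "LabLexicon":
        synonym_map: dict[str, str] = {}
        for canonical, aliases in config["tests"].items():
            synonym_map[normalize(canonical)] = canonical
            for alias in aliases or []:
                synonym_map[normalize(alias)] = canonical
        panel_map = {
            normalize(name): tuple(members)
            for name, members in config.get("panels", {}).items()
        }
        return cls(synonym_map=synonym_map, panel_map=panel_map)

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None) -> "LabLexicon":
        path = _data_path("lab_lexicon.yaml") if path is None else Path(path)
        return cls.from_config(yaml.safe_load(path.read_text()))


def match_lab_request(request_text: str, lexicon: LabLexicon) -> list[str]:
    """Map a free-text lab request to canonical test names.

    Best-match order: exact alias > panel name > longest alias substring.
    Panels expand to their member tests.  A request matching nothing
    returns an empty list — the caller renders "NA".
    """
    text = normalize(request_text)
    if not text:
        return []
    # exact alias beats everything
    if text in lexicon.synonym_map:
        return [lexicon.synonym_map[text]]
    if text in lexicon.panel_map:
        return list(lexicon.panel_map[text])

    # substring scan: longest aliases claim their spans first, no overlaps
    candidates: list[tuple[int, int, tuple[str, ...]]] = []
    entries: list[tuple[str, tuple[str, ...]]] = [
        (alias, (canonical,)) for alias, canonical in lexicon.synonym_map.items()
    ] + [(panel, members) for panel, members in lexicon.panel_map.items()]
    for alias, targets in entries:
        for m in re.finditer(rf"(?<![a-z0-9]){re.escape(alias)}(?![a-z0-9])", text):
            candidates.append((m.start(), m.end(), targets))
    # longer matches first; earlier position breaks ties
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    claimed: list[tuple[int, int]] = []
    hits: list[tuple[int, tuple[str, ...]]] = []
    for start, end, targets in candidates:
        if any(start < e and s < end for s, e in claimed):
            continue
        claimed.append((start, end))
        hits.append((start, targets))
    out: list[str] = []
    for _, targets in sorted(hits):
        for t in targets:
            if t not in out:
                out.append(t)
    return out


# --------------------------------------------------------------------------
# Imaging


@dataclass(frozen=True)
class ImagingLexicon:
    modality_keywords: dict[Modality, tuple[str, ...]]
    region_keywords: dict[str, tuple[str, ...]]
    # special exam name -> (modality, region or None)
    special_map: dict[str, tuple[Modality, Optional[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, Modality] = {}
        for modality, kws in self.modality_keywords.items():
            for kw in kws:
                if kw in seen and seen[kw] != modality:
                    raise ValueError(f"keyword {kw!r} under two modalities")
                seen[kw] = modality
        seen_r: dict[str, str] = {}
        for region, kws in self.region_keywords.items():
            for kw in kws:
                if kw in seen_r and seen_r[kw] != region:
                    raise ValueError(f"keyword {kw!r} under two regions")
                seen_r[kw] = region

    @classmethod
    def from_config(cls, config: dict) -> "ImagingLexicon":
        modality_keywords = {
            Modality(m): tuple(normalize(k) for k in kws)
            for m, kws in config["modalities"].items()
        }
        region_keywords = {
            r: tuple(normalize(k) for k in kws)
            for r, kws in config["regions"].items()
        }
        special_map = {}
        for name, spec in config.get("special_exams", {}).items():
            special_map[normalize(name)] = (
                Modality(spec["modality"]),
                spec.get("region"),
            )
        return cls(modality_keywords, region_keywords, special_map)

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None) -> "ImagingLexicon":
        path = _data_path("imaging_lexicon.yaml") if path is None else Path(path)
        return cls.from_config(yaml.safe_load(path.read_text()))

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_keywords)


class AmbiguousRequestError(ValueError):
    """Two modalities' (or regions') keywords both matched one request."""


def _kw_hit(keyword: str, text: str) -> bool:
    return re.search(rf"(?<![a-z0-9]){re.escape(keyword)}(?![a-z0-9])", text) is not None


def classify_imaging_request(
    request_text: str, lexicon: ImagingLexicon
) -> Optional[tuple[Modality, str]]:
    """Extract the unique (modality, region) named by an imaging request.

    The special-exam map is applied before the keyword scan (MRCP, CT
    urography, ...).  If no modality or no region keyword occurs, the
    result is absent.
    """
    text = normalize(request_text)
    modality: Optional[Modality] = None
    region: Optional[str] = None
    for name, (m, r) in lexicon.special_map.items():
        if _kw_hit(name, text):
            modality = m
            if r is not None:
                region = r
            break
    if modality is None:
        hits = [
            m
            for m, kws in lexicon.modality_keywords.items()
            if any(_kw_hit(k, text) for k in kws)
        ]
        if len(hits) > 1:
            raise AmbiguousRequestError(
                f"request {request_text!r} matches modalities {sorted(h.value for h in hits)}"
            )
        modality = hits[0] if hits else None
    if region is None:
        hits_r = [
            r
            for r, kws in lexicon.region_keywords.items()
            if any(_kw_hit(k, text) for k in kws)
        ]
        if len(hits_r) > 1:
            raise AmbiguousRequestError(
                f"request {request_text!r} matches regions {sorted(hits_r)}"
            )
        region = hits_r[0] if hits_r else None
    if modality is None or region is None:
        return None
    return modality, region


# --------------------------------------------------------------------------
# Diagnosis


@dataclass(frozen=True)
class DiagnosisLexicon:
    phrasings: dict[Pathology, tuple[str, ...]]  # normalized accepted phrasings

    def __post_init__(self) -> None:
        seen: dict[str, Pathology] = {}
        for pathology, terms in self.phrasings.items():
            for t in terms:
                if t in seen and seen[t] != pathology:
                    raise ValueError(f"phrasing {t!r} under two pathologies")
                seen[t] = pathology

    @classmethod
    def from_config(cls, config: dict) -> "DiagnosisLexicon":
        return cls(
            {
                Pathology(p): tuple(
                    dict.fromkeys([normalize(p)] + [normalize(t) for t in terms or []])
                )
                for p, terms in config["pathologies"].items()
            }
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path, None] = None) -> "DiagnosisLexicon":
        path = _data_path("diagnosis_lexicon.yaml") if path is None else Path(path)
        return cls.from_config(yaml.safe_load(path.read_text()))


_LIST_MARKER_RE = re.compile(r"(?:^|\s)(?:\d+\s*[.):]|[-*•])\s+")
_SEGMENT_SPLIT_RE = re.compile(r"[;\n]|(?<=[.!?])\s+")


def segment_diagnoses(diagnosis_text: str) -> list[str]:
    """Split a diagnosis span into individual diagnosis mentions.

    Splits on numbered/bulleted list markers, newlines, semicolons and
    sentence breaks, then on " and " / " with " so compound phrases yield
    their leading mention first.
    """
    text = _LIST_MARKER_RE.sub("\n", diagnosis_text)
    segments: list[str] = []
    for chunk in _SEGMENT_SPLIT_RE.split(text):
        if chunk is None:
            continue
        for piece in re.split(r"\s+(?:and|with)\s+", chunk):
            piece = piece.strip(" .,:")
            if piece:
                segments.append(piece)
    return segments


def match_diagnosis(
    diagnosis_text: str, gold: Pathology, lexicon: DiagnosisLexicon
) -> bool:
    """Does the *first* diagnosis mentioned name the gold pathology?

    Only the first segment is scanned (case-insensitively) for the gold
    pathology name or an accepted alternative phrasing; later mentions do
    not count.
    """
    segments = segment_diagnoses(diagnosis_text)
    if not segments:
        return False
    first = normalize(segments[0])
    return any(
        re.search(rf"(?<![a-z0-9]){re.escape(term)}(?![a-z0-9])", first)
        for term in lexicon.phrasings[gold]
    )


def load_default_lexicons() -> tuple[LabLexicon, ImagingLexicon, DiagnosisLexicon]:
    return (
        LabLexicon.from_yaml(),
        ImagingLexicon.from_yaml(),
        DiagnosisLexicon.from_yaml(),
    )
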