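"""Dataset construction: filtering, sections, windows, assembly, FI."""

from datetime import datetime, timedelta

import pytest

from cdmbench.builder import (
    FIPrompt,
    RawAdmissionBundle,
    RawLabEvent,
    RawRadiologyNote,
    build_dataset,
    build_fi_record,
    check_primary_discharge_diagnosis,
    collect_labs,
    collect_reports,
    extract_findings,
    extract_sections,
    filter_target_admissions,
    load_icd_code_sets,
    load_raw_tables,
)
from cdmbench.environment import TokenBudget, first_words_summarizer, word_token_counter
from cdmbench.records import Modality, Pathology, RadiologyReport, write_cases
from cdmbench.synthetic import (
    BASE_ADMIT,
    VIOLATION_REASONS,
    CaseProfile,
    generate_case,
    generate_raw_tables,
    write_raw_tables,
)

ADMIT = datetime(2130, 1, 1, 8, 0)

SUMMARY = """Chief Complaint:
abdominal pain

History of Present Illness:
Pain in the right lower quadrant since yesterday.

Physical Exam:
Tender RLQ, guarding.

Discharge Diagnosis:
1. Acute appendicitis
2. Hypertension

Discharge Condition:
Stable.
"""


def _bundle(**overrides):
    defaults = dict(
        patient_id="p1",
        admission_id="a1",
        admit_time=ADMIT,
        icd_diagnoses=(("K3580", 10),),
        discharge_summary_text=SUMMARY,
    )
    defaults.update(overrides)
    return RawAdmissionBundle(**defaults)


def _lab(name="lipase", hours_after_admit=1.0, hadm="a1", value=80.0):
    return RawLabEvent(
        name=name,
        value=value,
        unit="U/L",
        ref_low=13.0,
        ref_high=60.0,
        chart_time=ADMIT + timedelta(hours=hours_after_admit),
        hadm_id=hadm,
    )


class TestSectionExtraction:
    def test_standard_headers(self):
        sections = extract_sections(SUMMARY)
        assert sections["hpi"].startswith("Pain in the right lower quadrant")
        assert sections["physical_exam"] == "Tender RLQ, guarding."
        assert sections["discharge_diagnosis"].startswith("1. Acute appendicitis")

    def test_missing_physical_exam_absent(self):
        text = SUMMARY.replace("Physical Exam:\nTender RLQ, guarding.\n\n", "")
        assert "physical_exam" not in extract_sections(text)

    def test_sections_bounded_by_unextracted_headers(self):
        sections = extract_sections(SUMMARY)
        assert "Hypertension" in sections["discharge_diagnosis"]
        assert "Stable" not in sections["discharge_diagnosis"]


class TestIcdFilter:
    def test_single_target_kept(self):
        kept = filter_target_admissions([_bundle()], load_icd_code_sets())
        assert kept == [(_bundle(), Pathology.APPENDICITIS)]

    def test_dual_pathology_dropped(self):
        b = _bundle(icd_diagnoses=(("K3580", 10), ("K859", 10)))
        assert filter_target_admissions([b], load_icd_code_sets()) == []

    def test_icd9_with_dots_matches(self):
        b = _bundle(icd_diagnoses=(("540.9", 9),))
        kept = filter_target_admissions([b], load_icd_code_sets())
        assert kept[0][1] is Pathology.APPENDICITIS

    def test_no_target_code_dropped(self):
        b = _bundle(icd_diagnoses=(("I10", 10),))
        assert filter_target_admissions([b], load_icd_code_sets()) == []

    def test_empty_code_set_is_configuration_error(self):
        with pytest.raises(ValueError, match="empty ICD code set"):
            filter_target_admissions([_bundle()], {Pathology.APPENDICITIS: []})


class TestDischargeDiagnosisCheck:
    def test_primary_target_kept(self, diagnosis_lexicon):
        keep, _ = check_primary_discharge_diagnosis(
            _bundle(), Pathology.APPENDICITIS, diagnosis_lexicon
        )
        assert keep

    def test_other_diagnosis_first_drops(self, diagnosis_lexicon):
        text = SUMMARY.replace("1. Acute appendicitis", "1. Sepsis\n2. Acute appendicitis")
        keep, reason = check_primary_discharge_diagnosis(
            _bundle(discharge_summary_text=text), Pathology.APPENDICITIS, diagnosis_lexicon
        )
        assert not keep and reason == "secondary_discharge_diagnosis"

    def test_missing_section_drops_with_reason(self, diagnosis_lexicon):
        text = SUMMARY.replace("Discharge Diagnosis:", "Notes:")
        keep, reason = check_primary_discharge_diagnosis(
            _bundle(discharge_summary_text=text), Pathology.APPENDICITIS, diagnosis_lexicon
        )
        assert not keep and reason == "no_discharge_diagnosis"


class TestCollectLabs:
    def test_repeated_test_keeps_first_entry(self, lab_lexicon):
        b = _bundle(lab_events=(_lab(hours_after_admit=6.0, value=90.0), _lab(hours_after_admit=1.0)))
        labs = collect_labs(b, lab_lexicon)
        assert len(labs) == 1
        assert labs[0].value == 80.0

    def test_unlinked_event_outside_window_excluded(self, lab_lexicon):
        b = _bundle(lab_events=(_lab(hours_after_admit=-30.0, hadm=None),))
        assert collect_labs(b, lab_lexicon) == []

    def test_unlinked_event_within_window_included(self, lab_lexicon):
        b = _bundle(lab_events=(_lab(hours_after_admit=-5.0, hadm=None),))
        assert len(collect_labs(b, lab_lexicon)) == 1

    def test_window_closed_at_24h(self, lab_lexicon):
        b = _bundle(lab_events=(_lab(hours_after_admit=-24.0, hadm=None),))
        assert len(collect_labs(b, lab_lexicon)) == 1

    def test_unlinked_event_attributable_elsewhere_excluded(self, lab_lexicon):
        other = (ADMIT - timedelta(days=2), ADMIT - timedelta(hours=2))
        b = _bundle(
            lab_events=(_lab(hours_after_admit=-5.0, hadm=None),),
            other_admission_windows=(other,),
        )
        assert collect_labs(b, lab_lexicon) == []

    def test_raw_names_canonicalized(self, lab_lexicon):
        b = _bundle(lab_events=(_lab(name="WBC", value=12.0),))
        assert collect_labs(b, lab_lexicon)[0].canonical_name == "white blood cell count"


NOTE_TEXT = (
    "EXAMINATION: CT ABDOMEN W/O CONTRAST\nTECHNIQUE: axial.\n"
    "FINDINGS: Dilated appendix with fat stranding.\n"
    "IMPRESSION: Acute appendicitis."
)


class TestCollectReports:
    def test_findings_only_no_impression(self, imaging_lexicon):
        note = RawRadiologyNote("CT ABDOMEN W/O CONTRAST", ADMIT, NOTE_TEXT, "a1")
        reports = collect_reports(_bundle(radiology_notes=(note,)), imaging_lexicon)
        assert len(reports) == 1
        assert reports[0].modality is Modality.CT and reports[0].region == "abdomen"
        assert "Dilated appendix" in reports[0].findings_text
        assert "Impression" not in reports[0].findings_text
        assert "Acute appendicitis" not in reports[0].findings_text

    def test_mrcp_classified_as_mri_abdomen(self, imaging_lexicon):
        text = "FINDINGS: Normal biliary tree.\nIMPRESSION: Normal."
        note = RawRadiologyNote("MRCP", ADMIT, text, "a1")
        reports = collect_reports(_bundle(radiology_notes=(note,)), imaging_lexicon)
        assert (reports[0].modality, reports[0].region) == (Modality.MRI, "abdomen")

    def test_empty_findings_dropped_and_logged(self, imaging_lexicon):
        from cdmbench.builder import BuildReport

        note = RawRadiologyNote(
            "CT ABDOMEN", ADMIT, "IMPRESSION: unremarkable.", "a1"
        )
        report = BuildReport()
        assert collect_reports(_bundle(radiology_notes=(note,)), imaging_lexicon, report=report) == []
        assert ("CT ABDOMEN", "empty_findings") in report.report_drops

    def test_extract_findings(self):
        assert extract_findings(NOTE_TEXT) == "Dilated appendix with fat stranding."


class TestFullPipeline:
    def test_planted_violations_each_dropped_once(self):
        bundles = generate_raw_tables(2, seed=2023, violation_plan=list(VIOLATION_REASONS))
        cases, report = build_dataset(bundles)
        assert len(cases) == 8
        assert dict(report.drop_reasons) == {r: 1 for r in VIOLATION_REASONS}
        report.validate()  # telescoping counts

    def test_no_violations_zero_drops(self):
        bundles = generate_raw_tables(5, seed=2023)
        cases, report = build_dataset(bundles)
        assert len(cases) == 20
        assert sum(report.drop_reasons.values()) == 0

    def test_empty_input(self):
        cases, report = build_dataset([])
        assert cases == []

    def test_builder_deterministic_byte_identical(self, tmp_path):
        bundles = generate_raw_tables(3, seed=2023, violation_plan=["no_labs"])
        paths = []
        for name in ("one.jsonl", "two.jsonl"):
            cases, _ = build_dataset(bundles)
            p = tmp_path / name
            write_cases(cases, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_csv_round_trip_matches_in_memory_build(self, tmp_path):
        bundles = generate_raw_tables(2, seed=2023, violation_plan=list(VIOLATION_REASONS))
        direct_cases, direct_report = build_dataset(bundles)
        write_raw_tables(bundles, tmp_path / "tables")
        loaded = load_raw_tables(tmp_path / "tables")
        csv_cases, csv_report = build_dataset(loaded)
        assert len(csv_cases) == len(direct_cases)
        assert dict(csv_report.drop_reasons) == dict(direct_report.drop_reasons)
        assert [c.case_id for c in csv_cases] == [c.case_id for c in direct_cases]


class TestFIPromptAssembly:
    def test_canonical_order(self, guideline, appendicitis_case):
        fi = build_fi_record(appendicitis_case, guideline)
        tags = [t for t, _ in fi.spans]
        assert tags[:3] == ["hpi", "pe", "labs"]
        assert set(tags[3:]) == {"imaging"}

    def test_imaging_sorted_by_chart_time(self, guideline):
        case = generate_case(CaseProfile(pathology=Pathology.APPENDICITIS, seed=3))
        t0 = case.reports[0].chart_time
        earlier = RadiologyReport(
            exam_name="CT ABDOMEN EARLY",
            modality=Modality.CT,
            region="abdomen",
            chart_time=t0 - timedelta(hours=1),
            findings_text="Equivocal early appearance.",
        )
        case = case.model_copy(update={"reports": case.reports + [earlier]})
        fi = build_fi_record(case, guideline)
        imaging = fi.span_texts("imaging")
        assert "EARLY" in imaging[0] and "EARLY" not in imaging[1]

    def test_only_guideline_relevant_labs_included(self, guideline, appendicitis_case):
        fi = build_fi_record(appendicitis_case, guideline)
        labs_span = fi.span_texts("labs")[0]
        relevant = set(guideline.all_relevant_tests())
        assert "white blood cell count" in labs_span
        assert "albumin" not in labs_span  # in no guideline category
        assert "albumin" not in relevant

    def test_chest_reports_excluded(self, guideline, appendicitis_case):
        fi = build_fi_record(appendicitis_case, guideline)
        assert not any("CHEST" in t for t in fi.span_texts("imaging"))

    def test_over_budget_output_fits_reserve(self, guideline, appendicitis_case):
        fixed = build_fi_record(appendicitis_case, guideline)
        no_imaging = FIPrompt(
            fixed.instructions, [s for s in fixed.spans if s[0] != "imaging"]
        )
        limit = word_token_counter(no_imaging.render()) + 40
        budget = TokenBudget(limit=limit)
        fi = build_fi_record(
            appendicitis_case, guideline, budget, first_words_summarizer(10)
        )
        assert budget.count(fi.render()) <= budget.limit - budget.reserve_tokens

    def test_summarizer_failure_falls_back_to_trimming(self, guideline, appendicitis_case):
        fixed = build_fi_record(appendicitis_case, guideline)
        no_imaging = FIPrompt(
            fixed.instructions, [s for s in fixed.spans if s[0] != "imaging"]
        )
        budget = TokenBudget(limit=word_token_counter(no_imaging.render()) + 40)

        def failing(_text):
            raise RuntimeError("no summarizer")

        fi = build_fi_record(appendicitis_case, guideline, budget, failing)
        assert budget.count(fi.render()) <= budget.usable
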