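"""Scoring rules, interpretation classification, and statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from cdmbench.evaluation import (
    CaseScore,
    classify_lab_value,
    compare_groups,
    per_class_accuracy,
    score_episode,
    score_interpretations,
    score_treatment_text,
)
from cdmbench.environment import run_episode
from cdmbench.records import Pathology, ProcedureRecord
from cdmbench.synthetic import (
    CaseProfile,
    generate_case,
    generate_interpretation_set,
    omniscient_script,
    scripted_agent,
)


class TestClassifyLabValue:
    @pytest.mark.parametrize(
        "value, low, high, expected",
        [
            (5.0, 3.5, 9.1, "within"),
            (2.0, 3.5, 9.1, "below"),
            (12.0, 3.5, 9.1, "above"),
            (3.5, 3.5, 9.1, "within"),  # inclusive lower bound
            (9.1, 3.5, 9.1, "within"),  # inclusive upper bound
            (2.0, None, 9.1, "within"),  # no low bound -> never below
            (12.0, 3.5, None, "within"),  # no high bound -> never above
            ("negative", 3.5, 9.1, None),  # non-numeric -> not classifiable
            ("4.2", 3.5, 9.1, "within"),  # numeric text parses
            (5.0, None, None, None),
        ],
    )
    def test_examples(self, value, low, high, expected):
        assert classify_lab_value(value, low, high) == expected


class TestScoreInterpretations:
    def test_perfect_labels(self):
        items = generate_interpretation_set(90, seed=1)
        labels = [i.gold_label for i in items]
        assert score_interpretations(labels, items) == {
            "below": 100.0, "within": 100.0, "above": 100.0
        }

    def test_constant_within_labels(self):
        items = generate_interpretation_set(90, seed=1)
        result = score_interpretations(["within"] * 90, items)
        assert result["within"] == 100.0
        assert result["below"] == 0.0 and result["above"] == 0.0

    def test_random_labels_near_chance(self):
        """Uniform random labels score ~33% per label (binomial CI)."""
        rng = np.random.default_rng(42)
        items = generate_interpretation_set(3000, seed=7)
        labels = [
            ("below", "within", "above")[i] for i in rng.integers(0, 3, size=3000)
        ]
        result = score_interpretations(labels, items)
        for label, acc in result.items():
            n = sum(1 for i in items if i.gold_label == label)
            margin = 100.0 * 4 * math.sqrt((1 / 3) * (2 / 3) / n)
            assert abs(acc - 100.0 / 3) < margin, (label, acc)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="not aligned"):
            score_interpretations(["below"], [])


def _score(pathology, correct, **kw):
    defaults = dict(
        case_id="x",
        pathology=pathology,
        diagnosed_correctly=correct,
        pe_first=True,
        pe_at_all=True,
        lab_categories_met={},
        imaging_requested=[],
        treatment_flags={},
    )
    defaults.update(kw)
    return CaseScore(**defaults)


class TestPerClassAccuracy:
    def test_examples(self):
        scores = [_score(Pathology.APPENDICITIS, i < 15) for i in range(20)]
        assert per_class_accuracy(scores, Pathology.APPENDICITIS) == 75.0
        scores_none = [_score(Pathology.PANCREATITIS, False) for _ in range(5)]
        assert per_class_accuracy(scores_none, Pathology.PANCREATITIS) == 0.0

    def test_no_cross_class_pooling(self):
        scores = [_score(Pathology.APPENDICITIS, True)] * 3 + [
            _score(Pathology.PANCREATITIS, False)
        ] * 3
        assert per_class_accuracy(scores, Pathology.APPENDICITIS) == 100.0
        assert per_class_accuracy(scores, Pathology.PANCREATITIS) == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            per_class_accuracy([], Pathology.APPENDICITIS)

    def test_agrees_with_brute_force_recount(self):
        rng = np.random.default_rng(17)
        pathologies = list(Pathology)
        for _ in range(100):
            scores = [
                _score(pathologies[rng.integers(0, 4)], bool(rng.integers(0, 2)))
                for _ in range(int(rng.integers(4, 40)))
            ]
            for p in pathologies:
                subset = [s for s in scores if s.pathology == p]
                if not subset:
                    continue
                brute = 100.0 * len([s for s in subset if s.diagnosed_correctly]) / len(subset)
                assert per_class_accuracy(scores, p) == pytest.approx(brute)


def _welch_reference(a, b):
    """Textbook Welch formula, independent of scipy.stats.ttest_ind."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        assert compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_bonferroni_multiplier(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(1, 1, 30)
        p1 = compare_groups(a, b, n_comparisons=1)
        p5 = compare_groups(a, b, n_comparisons=5)
        assert p5 == pytest.approx(min(1.0, p1 * 5))

    def test_clearly_separated_groups(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(5, 1, 20)
        assert compare_groups(a, b, n_comparisons=5) < 0.001

    def test_matches_textbook_welch_on_random_pairs(self):
        rng = np.random.default_rng(2023)
        for _ in range(100):
            na, nb = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            assert compare_groups(a, b) == pytest.approx(
                min(1.0, _welch_reference(a, b)), abs=1e-10
            )

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


APPENDECTOMY = [ProcedureRecord(free_text="Laparoscopic appendectomy", source="discharge_summary")]


class TestTreatmentScoring:
    def test_full_plan_recommended(self, guideline):
        flags = score_treatment_text(
            "Perform appendectomy, start IV fluids and analgesia, monitor closely, "
            "begin antibiotics.",
            Pathology.APPENDICITIS,
            guideline,
            APPENDECTOMY,
        )
        assert flags["appendectomy"] == "recommended"
        assert flags["antibiotics"] == "recommended"
        assert flags["support"] == "recommended"
        assert flags["drainage"] == "not_applicable"

    def test_pancreatitis_support_needs_all_three(self, guideline):
        flags = score_treatment_text(
            "Aggressive IV fluids.", Pathology.PANCREATITIS, guideline, []
        )
        assert flags["support"] == "missed"
        flags_full = score_treatment_text(
            "IV fluids, pain control with analgesia, close monitoring.",
            Pathology.PANCREATITIS,
            guideline,
            [],
        )
        assert flags_full["support"] == "recommended"

    def test_appendicitis_support_any_of_three(self, guideline):
        flags = score_treatment_text(
            "Monitoring overnight.", Pathology.APPENDICITIS, guideline, []
        )
        assert flags["support"] == "recommended"

    def test_empty_text_misses_everything_expected(self, guideline):
        flags = score_treatment_text("", Pathology.APPENDICITIS, guideline, APPENDECTOMY)
        assert flags["appendectomy"] == "missed"
        assert flags["antibiotics"] == "missed"
        assert flags["support"] == "missed"

    def test_negated_mention_does_not_count(self, guideline):
        flags = score_treatment_text(
            "Do not perform appendectomy at this time.",
            Pathology.APPENDICITIS,
            guideline,
            APPENDECTOMY,
        )
        assert flags["appendectomy"] == "missed"

    def test_coded_procedure_predicate(self, guideline):
        received = [ProcedureRecord(code="0DTJ4ZZ", source="coded_table")]
        flags = score_treatment_text(
            "appendectomy", Pathology.APPENDICITIS, guideline, received
        )
        assert flags["appendectomy"] == "recommended"


class TestScoreEpisode:
    def _episode(self, case, guideline, env_config, script=None):
        agent = scripted_agent(script or omniscient_script(case, guideline))
        return run_episode(case, agent, env_config())

    def test_single_category_member_suffices(
        self, guideline, env_config, appendicitis_case, diagnosis_lexicon
    ):
        ep = self._episode(
            appendicitis_case, guideline, env_config,
            [
                "Action: Laboratory Tests\nAction Input: WBC",
                "Final Diagnosis: acute appendicitis\nTreatment: appendectomy, fluids, antibiotics",
            ],
        )
        score = score_episode(ep, appendicitis_case, guideline, diagnosis_lexicon)
        assert score.lab_categories_met == {"inflammation": True}

    def test_wrong_diagnosis_empties_treatment_flags(
        self, guideline, env_config, appendicitis_case, diagnosis_lexicon
    ):
        ep = self._episode(
            appendicitis_case, guideline, env_config,
            ["Final Diagnosis: acute pancreatitis\nTreatment: appendectomy and fluids"],
        )
        score = score_episode(ep, appendicitis_case, guideline, diagnosis_lexicon)
        assert not score.diagnosed_correctly
        assert score.treatment_flags == {}

    def test_treatment_conditioning_metamorphic(
        self, guideline, env_config, appendicitis_case, diagnosis_lexicon
    ):
        """Flipping the final diagnosis to a wrong one empties the
        treatment flags of an otherwise identical episode."""
        ep = self._episode(appendicitis_case, guideline, env_config)
        good = score_episode(ep, appendicitis_case, guideline, diagnosis_lexicon)
        assert good.treatment_flags
        flipped = ep.model_copy(update={"final_diagnosis_text": "acute cholecystitis"})
        bad = score_episode(flipped, appendicitis_case, guideline, diagnosis_lexicon)
        assert bad.treatment_flags == {}

    def test_case_specific_not_applicable_without_procedure(
        self, guideline, env_config, diagnosis_lexicon
    ):
        case = generate_case(
            CaseProfile(pathology=Pathology.DIVERTICULITIS, severity="uncomplicated", seed=4)
        )
        ep = self._episode(case, guideline, env_config)
        score = score_episode(ep, case, guideline, diagnosis_lexicon)
        assert score.diagnosed_correctly
        assert score.treatment_flags["colectomy"] == "not_applicable"

    def test_missing_guideline_is_configuration_error(
        self, env_config, appendicitis_case, diagnosis_lexicon, guideline
    ):
        from cdmbench.evaluation import GuidelineSpec

        ep = self._episode(appendicitis_case, guideline, env_config)
        partial = GuidelineSpec(
            pathologies={
                p: g for p, g in guideline.pathologies.items()
                if p is not Pathology.APPENDICITIS
            },
            treatment_keywords=guideline.treatment_keywords,
            support_keywords=guideline.support_keywords,
        )
        with pytest.raises(ValueError, match="no guideline"):
            score_episode(ep, appendicitis_case, partial, diagnosis_lexicon)
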