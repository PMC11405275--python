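import numpy as np
import pytest

from cdmbench.environment import EnvConfig, TokenBudget
from cdmbench.evaluation import GuidelineSpec
from cdmbench.lexicon import DiagnosisLexicon, ImagingLexicon, LabLexicon
from cdmbench.records import Pathology
from cdmbench.synthetic import CaseProfile, generate_case, generate_cases


@pytest.fixture(scope="session")
def lab_lexicon():
    return LabLexicon.from_yaml()


@pytest.fixture(scope="session")
def imaging_lexicon():
    return ImagingLexicon.from_yaml()


@pytest.fixture(scope="session")
def diagnosis_lexicon():
    return DiagnosisLexicon.from_yaml()


@pytest.fixture(scope="session")
def guideline():
    return GuidelineSpec.from_yaml()


@pytest.fixture(scope="session")
def small_cohort():
    """Two cases per pathology (one of them complicated)."""
    return generate_cases(2, seed=2023, complicated_every=2)


@pytest.fixture
def appendicitis_case():
    return generate_case(CaseProfile(pathology=Pathology.APPENDICITIS, seed=7))


@pytest.fixture
def env_config(lab_lexicon, imaging_lexicon):
    def make(**overrides):
        defaults = dict(
            lab_lexicon=lab_lexicon,
            imaging_lexicon=imaging_lexicon,
            budget=TokenBudget(),
        )
        defaults.update(overrides)
        return EnvConfig(**defaults)

    return make


class RecordingAgent:
    """Wraps an agent, recording every prompt it is handed."""

    def __init__(self, inner):
        self.inner = inner
        self.prompts: list[str] = []

    def __call__(self, prompt, stop=()):
        self.prompts.append(prompt)
        return self.inner(prompt, stop=stop)

    def summarize(self, text):
        return self.inner.summarize(text)


@pytest.fixture
def recording():
    return RecordingAgent
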