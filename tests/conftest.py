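from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from ptlnlp.lexicon import load_lexicon
from ptlnlp.preprocess import preprocess_text
from ptlnlp.visits import ClinicalNote

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture
def make_sentence(lexicon):
    """Build a preprocessed Sentence from raw text (first sentence)."""

    def _make(text: str, note_id: str = "n1"):
        sentences = preprocess_text(text, lexicon.corrections, note_id)
        assert sentences, f"no sentence produced from {text!r}"
        return sentences[0]

    return _make


@pytest.fixture
def make_note():
    def _make(text: str, note_id: str = "n1", encounter_id: str = "e1",
              note_type: str = "triage note",
              when: datetime = datetime(2020, 1, 1, 12, 0)):
        return ClinicalNote(note_id, encounter_id, note_type, when, text)

    return _make
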