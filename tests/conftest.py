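from __future__ import annotations

import pytest

from lexatlas.lexicon import Lexicon, WordEntry
from lexatlas.reference import reference_lexicon, reference_questionnaire


@pytest.fixture(scope="session")
def ref_lexicon() -> Lexicon:
    return reference_lexicon()


@pytest.fixture(scope="session")
def ref_questionnaire():
    return reference_questionnaire()


@pytest.fixture
def small_lexicon() -> Lexicon:
    """Three scored adjectives, one of them an anchor."""
    return Lexicon([
        WordEntry("humble", "adjective", "personality", 1.0, -2.0,
                  anchor=True, provenance="judged"),
        WordEntry("friendly", "adjective", "personality", 2.0, 0.0,
                  provenance="judged"),
        WordEntry("vague", "adjective", "personality", -1.0, 0.0,
                  provenance="judged"),
    ])
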