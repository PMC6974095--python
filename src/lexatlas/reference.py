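"""Published reference tables of the atlas, as in-package fixtures.

These small tables ship with the package so that questionnaire and
measure computations can be exercised against the published atlas
without any external data:

* the catalogue summary (words per part of speech and domain),
* the per-cell example words (one personality trait, emotion and
  behaviour for each of the 25 cells),
* the published 12-item dipole questionnaire and its cell pairs,
* the word-to-cell examples used for construct mapping ('ordinary',
  'kill', 'love'), and the two senses of 'humble'.
"""

from __future__ import annotations

from .design import DipolePairing, Questionnaire, QuestionnaireItem
from .grid import AtlasCell
from .lexicon import Lexicon, WordEntry

#: Catalogue summary: words per part of speech (rows) and domain (columns).
CATALOGUE_SUMMARY: dict[str, dict[str, int]] = {
    "adjective": {"behaviour": 0, "emotion": 0, "personality": 4356, "power": 171},
    "idiom":     {"behaviour": 3675, "emotion": 532, "personality": 1915, "power": 464},
    "noun":      {"behaviour": 1345, "emotion": 2705, "personality": 1047, "power": 1335},
    "verb":      {"behaviour": 3124, "emotion": 0, "personality": 0, "power": 0},
}

#: Printed marginals of the catalogue summary.
CATALOGUE_DOMAIN_TOTALS: dict[str, int] = {
    "behaviour": 8144, "emotion": 3237, "personality": 7318, "power": 1970,
}
CATALOGUE_GRAND_TOTAL: int = 20669

#: Example words per cell: domain -> {(affiliation, dominance): lemma}.
#: Emotions are abstract nouns, behaviours verbs, personality adjectives.
CELL_EXAMPLES: dict[str, dict[tuple[int, int], str]] = {
    "emotion": {
        (-2, 2): "hate", (-1, 2): "arrogance", (0, 2): "enthusiasm",
        (1, 2): "courage", (2, 2): "euphoria",
        (-2, 1): "contempt", (-1, 1): "frustration", (0, 1): "interest",
        (1, 1): "confidence", (2, 1): "happiness",
        (-2, 0): "detachment", (-1, 0): "instability", (0, 0): "consciousness",
        (1, 0): "stability", (2, 0): "harmony",
        (-2, -1): "sadness", (-1, -1): "anxiety", (0, -1): "disinterest",
        (1, -1): "appreciation", (2, -1): "admiration",
        (-2, -2): "dread", (-1, -2): "cowardice", (0, -2): "fatigue",
        (1, -2): "humility", (2, -2): "love",
    },
    "behaviour": {
        (-2, 2): "attack", (-1, 2): "defy", (0, 2): "pioneer",
        (1, 2): "advance", (2, 2): "captivate",
        (-2, 1): "slander", (-1, 1): "argue", (0, 1): "action",
        (1, 1): "negotiate", (2, 1): "laugh",
        (-2, 0): "dissociate", (-1, 0): "neglect", (0, 0): "sense",
        (1, 0): "attend", (2, 0): "attach",
        (-2, -1): "lament", (-1, -1): "complain", (0, -1): "inaction",
        (1, -1): "relent", (2, -1): "endorse",
        (-2, -2): "deflate", (-1, -2): "surrender", (0, -2): "stagnate",
        (1, -2): "obey", (2, -2): "nurse",
    },
    "personality": {
        (-2, 2): "cruel", (-1, 2): "arrogant", (0, 2): "energetic",
        (1, 2): "brave", (2, 2): "charismatic",
        (-2, 1): "nasty", (-1, 1): "inflexible", (0, 1): "efficient",
        (1, 1): "confident", (2, 1): "joyful",
        (-2, 0): "unfriendly", (-1, 0): "vague", (0, 0): "alive",
        (1, 0): "clear", (2, 0): "friendly",
        (-2, -1): "joyless", (-1, -1): "worried", (0, -1): "inefficient",
        (1, -1): "flexible", (2, -1): "nice",
        (-2, -2): "morose", (-1, -2): "coward", (0, -2): "apathetic",
        (1, -2): "humble", (2, -2): "tender",
    },
}

_DOMAIN_POS = {"emotion": "noun", "behaviour": "verb", "personality": "adjective"}

#: The published 12-item dipole test: (negative word, positive word,
#: negative cell, positive cell).  All items are adjectives.
QUESTIONNAIRE_ITEMS: tuple[tuple[str, str, tuple[int, int], tuple[int, int]], ...] = (
    ("despondent", "hopeful", (-2, -2), (2, 2)),
    ("sad", "happy", (-2, -1), (2, 1)),
    ("uncooperative", "cooperative", (-2, 0), (2, 0)),
    ("disagreeable", "agreeable", (-2, 1), (2, -1)),
    ("unkind", "kind", (-2, 2), (2, -2)),
    ("cowardly", "courageous", (-1, -2), (1, 2)),
    ("discontent", "content", (-1, -1), (1, 1)),
    ("untalkative", "talkative", (-1, 0), (1, 0)),
    ("unhelpful", "helpful", (-1, 1), (1, -1)),
    ("selfish", "unselfish", (-1, 2), (1, -2)),
    ("unambitious", "ambitious", (0, -2), (0, 2)),
    ("inactive", "active", (0, -1), (0, 1)),
)

#: Word-to-cell examples from the construct-mapping study.
MAPPING_EXAMPLES: tuple[tuple[str, str, str, tuple[int, int]], ...] = (
    ("ordinary", "adjective", "personality", (1, 0)),
    ("kill", "verb", "behaviour", (-2, 2)),
    ("love", "noun", "emotion", (2, -2)),
    # 'humble' carries different cells under different parts of speech
    ("humble", "verb", "behaviour", (-2, 1)),
)


def reference_lexicon() -> Lexicon:
    """A small scored lexicon of the published example and questionnaire
    words, each at its printed cell (anchored, provenance 'judged')."""
    lx = Lexicon()

    def _add(lemma: str, pos: str, domain: str, cell: tuple[int, int]) -> None:
        if (lemma, pos) in lx:
            return
        lx.add(WordEntry(lemma=lemma, pos=pos, domain=domain,
                         affiliation=float(cell[0]), dominance=float(cell[1]),
                         anchor=True, provenance="judged"))

    for domain, cells in CELL_EXAMPLES.items():
        for cell, lemma in cells.items():
            _add(lemma, _DOMAIN_POS[domain], domain, cell)
    for neg, pos_w, cneg, cpos in QUESTIONNAIRE_ITEMS:
        _add(neg, "adjective", "personality", cneg)
        _add(pos_w, "adjective", "personality", cpos)
    for lemma, pos, domain, cell in MAPPING_EXAMPLES:
        _add(lemma, pos, domain, cell)
    return lx


def reference_questionnaire() -> Questionnaire:
    """The published 12-item test as a :class:`Questionnaire`."""
    items = [
        QuestionnaireItem(negative=(neg, "adjective"),
                          positive=(pos, "adjective"),
                          cells=(AtlasCell(*cneg), AtlasCell(*cpos)))
        for neg, pos, cneg, cpos in QUESTIONNAIRE_ITEMS
    ]
    return Questionnaire(items=items)


def reference_pairing() -> DipolePairing:
    """The cell pairing underlying the published test (reflection pairs)."""
    return DipolePairing.from_pairs(
        [(AtlasCell(*a), AtlasCell(*b)) for _, _, a, b in QUESTIONNAIRE_ITEMS])
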