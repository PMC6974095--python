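import math

import numpy as np
import pytest
from scipy.stats import chisquare

from lexatlas.design import (DipolePairing, Questionnaire, QuestionnaireItem,
                             enumerate_matchings_bruteforce,
                             max_avg_distance_matching, min_questions,
                             reflection_pairing, sample_matchings,
                             score_responses, select_question_words)
from lexatlas.design import test_measures as questionnaire_measures
from lexatlas.errors import InsufficiencyError, ValidationError
from lexatlas.grid import NON_CENTRE_CELLS, AtlasCell
from lexatlas.lexicon import Lexicon, WordEntry
from lexatlas.reference import reference_pairing, reference_questionnaire


class TestMinQuestions:
    @pytest.mark.parametrize("n,per,expected", [
        (24, 2, 12), (25, 2, 13), (8, 2, 4), (1, 1, 1), (7, 3, 3)])
    def test_covering_bound(self, n, per, expected):
        assert min_questions(n, per) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            min_questions(0, 2)


def _cells(*pairs):
    return [AtlasCell(a, d) for a, d in pairs]


GRID3 = _cells(*[(a, d) for a in (-1, 0, 1) for d in (-1, 0, 1)
                 if (a, d) != (0, 0)])


class TestBruteForce:
    @pytest.mark.parametrize("cells,count", [
        (_cells((0, 1), (0, -1)), 1),
        (_cells((0, 1), (0, -1), (1, 0), (-1, 0)), 3),
        (GRID3, 105),
    ])
    def test_double_factorial_counts(self, cells, count):
        assert len(enumerate_matchings_bruteforce(cells)) == count

    def test_odd_count_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_matchings_bruteforce(_cells((0, 1)))

    def test_scale_limit(self):
        with pytest.raises(ValidationError):
            enumerate_matchings_bruteforce(list(NON_CENTRE_CELLS))


class TestExactSearch:
    def test_agrees_with_bruteforce_on_3x3_grid(self):
        res = max_avg_distance_matching(GRID3)
        brute = enumerate_matchings_bruteforce(GRID3)
        best = max(m for _, m in brute)
        brute_set = {mt for mt, m in brute if abs(m - best) <= 1e-9}
        assert res.max_mean_distance == pytest.approx(best)
        assert {m.pairs for m in res.maximizers} == brute_set

    @pytest.mark.parametrize("trial", range(40))
    def test_agrees_with_bruteforce_on_random_subsets(self, trial):
        rng = np.random.default_rng(trial)
        size = int(rng.choice([4, 6, 8, 10]))
        idx = rng.choice(len(NON_CENTRE_CELLS), size=size, replace=False)
        cells = [NON_CENTRE_CELLS[i] for i in idx]
        res = max_avg_distance_matching(cells)
        brute = enumerate_matchings_bruteforce(cells)
        best = max(m for _, m in brute)
        brute_set = {mt for mt, m in brute if abs(m - best) <= 1e-9}
        assert res.max_mean_distance == pytest.approx(best)
        assert {m.pairs for m in res.maximizers} == brute_set

    def test_atlas_has_sixteen_maximizers_at_published_mean(self):
        res = max_avg_distance_matching(NON_CENTRE_CELLS)
        assert res.maximizer_count == 16
        assert round(res.max_mean_distance, 1) == 3.9
        assert res.max_mean_distance == pytest.approx(
            (12 + 12 * math.sqrt(2) + 8 * math.sqrt(5)) / 12)

    def test_reflection_pairing_is_always_a_maximizer(self):
        res = max_avg_distance_matching(NON_CENTRE_CELLS)
        refl = reflection_pairing()
        assert any(m.pairs == refl.pairs for m in res.maximizers)

    def test_every_maximizer_reflects_the_off_axis_knight_cells(self):
        # the eight cells (+-2,+-1),(+-1,+-2) admit no collinear swap, so
        # every maximizer pairs them with their exact reflection
        knights = {AtlasCell(a, d) for a, d in
                   [(2, 1), (2, -1), (-2, 1), (-2, -1),
                    (1, 2), (1, -2), (-1, 2), (-1, -2)]}
        res = max_avg_distance_matching(NON_CENTRE_CELLS)
        for m in res.maximizers:
            for a, b in m.pairs:
                if a in knights or b in knights:
                    assert b == a.reflected()

    def test_maximizer_count_factorises_over_origin_lines(self):
        # each of the 4 origin lines with two cells per side (both axes,
        # both diagonals) admits one independent collinear swap: 2^4 ties
        res = max_avg_distance_matching(NON_CENTRE_CELLS)
        lines = 4
        assert res.maximizer_count == 2 ** lines


class TestSampling:
    def test_sample_max_never_exceeds_exact_optimum(self):
        exact = max_avg_distance_matching(NON_CENTRE_CELLS)
        summary = sample_matchings(NON_CENTRE_CELLS, 20000, seed=1)
        assert summary.max <= exact.max_mean_distance + 1e-12

    def test_reproducible_for_fixed_seed(self):
        a = sample_matchings(NON_CENTRE_CELLS, 5000, seed=3)
        b = sample_matchings(NON_CENTRE_CELLS, 5000, seed=3)
        assert a == b
        c = sample_matchings(NON_CENTRE_CELLS, 5000, seed=4)
        assert c.mean != a.mean

    def test_uniform_over_the_three_matchings_of_four_cells(self):
        cells = _cells((0, 1), (0, -1), (1, 0), (-1, 0))
        enumerated = {mt for mt, _ in enumerate_matchings_bruteforce(cells)}
        summary = sample_matchings(cells, 30000, seed=2, return_counts=True)
        assert set(summary.counts) <= enumerated
        assert len(summary.counts) == 3
        stat = chisquare(list(summary.counts.values()))
        assert stat.pvalue > 0.001


class TestDipolePairing:
    def test_pairing_validates_disjoint_non_centre_cells(self):
        with pytest.raises(ValidationError):
            DipolePairing.from_pairs([(AtlasCell(0, 0), AtlasCell(1, 1))])
        with pytest.raises(ValidationError):
            DipolePairing.from_pairs([(AtlasCell(1, 1), AtlasCell(1, 1))])
        with pytest.raises(ValidationError):
            DipolePairing.from_pairs([
                (AtlasCell(1, 1), AtlasCell(2, 2)),
                (AtlasCell(1, 1), AtlasCell(-1, -1))])

    def test_reference_pairing_mean_distance(self):
        assert reference_pairing().mean_distance == pytest.approx(
            3.9049, abs=1e-4)


def _pool_lexicon():
    """Lexicon and pool covering all 12 reflection cell pairs."""
    lx = Lexicon()
    pool = []
    for i, (ca, cb) in enumerate(reference_pairing().pairs):
        for dup in ("x", "y"):
            neg = f"{dup}neg{i:02d}"
            pos = f"{dup}pos{i:02d}"
            lx.add(WordEntry(neg, "adjective", "personality",
                             float(ca.affiliation), float(ca.dominance)))
            lx.add(WordEntry(pos, "adjective", "personality",
                             float(cb.affiliation), float(cb.dominance)))
            pool.append(((neg, "adjective"), (pos, "adjective")))
    return lx, pool


class TestSelectQuestionWords:
    def test_reference_pool_reproduces_printed_first_item(self, ref_lexicon):
        from lexatlas.reference import QUESTIONNAIRE_ITEMS
        pool = [((n, "adjective"), (p, "adjective"))
                for n, p, _, _ in QUESTIONNAIRE_ITEMS]
        q = select_question_words(reference_pairing(), pool, ref_lexicon)
        first = q.items[0]
        assert first.negative == ("despondent", "adjective")
        assert first.positive == ("hopeful", "adjective")
        assert first.cells == (AtlasCell(-2, -2), AtlasCell(2, 2))

    def test_missing_cell_pair_raises_insufficiency(self):
        lx, pool = _pool_lexicon()
        target = (AtlasCell(0, -2), AtlasCell(0, 2))
        trimmed = [pair for pair in pool
                   if lx[pair[0][0], pair[0][1]].cell != target[0]]
        with pytest.raises(InsufficiencyError) as exc:
            select_question_words(reference_pairing(), trimmed, lx)
        assert exc.value.cell_pair == target

    def test_lexicographically_first_eligible_pair_chosen(self):
        lx, pool = _pool_lexicon()
        q1 = select_question_words(reference_pairing(), pool, lx)
        q2 = select_question_words(reference_pairing(), list(reversed(pool)), lx)
        assert q1.items == q2.items
        assert all(it.negative[0].startswith("x") for it in q1.items)

    def test_full_questionnaire_covers_all_cells(self):
        lx, pool = _pool_lexicon()
        q = select_question_words(reference_pairing(), pool, lx)
        cells = {c for it in q.items for c in it.cells}
        assert len(q.items) == 12 and len(cells) == 24


class TestTestMeasures:
    def test_published_atlas_row(self, ref_lexicon, ref_questionnaire):
        m = questionnaire_measures(ref_questionnaire, ref_lexicon)
        assert m.diffusion == 0.0
        assert m.completeness == 1.0
        assert round(m.discrimination, 1) == 3.9
        assert m.dipole_count == 12
        assert m.display() == {"diffusion": "0%", "discrimination": "3.9",
                               "completeness": "100%", "dipoles": "12"}

    def test_single_item_questionnaire(self, ref_lexicon):
        q = Questionnaire(items=[QuestionnaireItem(
            negative=("despondent", "adjective"),
            positive=("hopeful", "adjective"),
            cells=(AtlasCell(-2, -2), AtlasCell(2, 2)))])
        m = questionnaire_measures(q, ref_lexicon)
        assert m.completeness == pytest.approx(2 / 24)
        assert m.discrimination == pytest.approx(4 * math.sqrt(2))
        assert m.diffusion == 0.0


class TestScoreResponses:
    def test_all_positive_profile_averages_right_hand_cells(
            self, ref_questionnaire):
        profile = score_responses(ref_questionnaire, ["positive"] * 12)
        # mean of the 12 printed right-hand cells
        assert profile.affiliation == pytest.approx(15 / 12)
        assert profile.dominance == pytest.approx(3 / 12)
        assert profile.n_answered == 12

    def test_all_na_yields_undefined_profile(self, ref_questionnaire):
        profile = score_responses(ref_questionnaire, ["n/a"] * 12)
        assert not profile.defined
        assert profile.n_answered == 0

    def test_mirror_items_answered_alike_cancel_to_origin(self):
        # a pair of items with swapped orientation: the same choice side
        # contributes opposite cells, so the profile collapses to (0, 0)
        item = QuestionnaireItem(negative=("sad", "adjective"),
                                 positive=("happy", "adjective"),
                                 cells=(AtlasCell(-2, -1), AtlasCell(2, 1)))
        mirror = QuestionnaireItem(negative=("happy", "adjective"),
                                   positive=("sad", "adjective"),
                                   cells=(AtlasCell(2, 1), AtlasCell(-2, -1)))
        q = Questionnaire(items=[item, mirror])
        profile = score_responses(q, ["positive", "positive"])
        assert (profile.affiliation, profile.dominance) == (0.0, 0.0)

    def test_length_mismatch_rejected(self, ref_questionnaire):
        with pytest.raises(ValidationError):
            score_responses(ref_questionnaire, ["positive"] * 11)

    def test_invalid_response_value_rejected(self, ref_questionnaire):
        with pytest.raises(ValidationError):
            score_responses(ref_questionnaire, ["maybe"] * 12)
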