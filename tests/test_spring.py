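import math
from dataclasses import replace

import numpy as np
import pytest

from lexatlas.errors import BootstrapError, ValidationError
from lexatlas.graph import ThesaurusGraph
from lexatlas.lexicon import Lexicon, WordEntry
from lexatlas.spring import (SpringConfig, equilibrium_position, initial_pass,
                             node_energy, propagate, relaxation_sweep,
                             total_energy)
from lexatlas.synth import (SynthParams, generate_graph, generate_lexicon)

from _oracles import centroid_fixed_point, grid_search_equilibrium

CFG = SpringConfig()


def _adj(lemma, a=None, d=None, anchor=False):
    return WordEntry(lemma, "adjective", "personality", a, d, anchor=anchor)


class TestNodeEnergy:
    def test_coincident_synonym_is_zero(self):
        assert node_energy((1, 1), [(1, 1)], [], CFG) == 0.0

    def test_coincident_antonym_closed_form(self):
        cfg = replace(CFG, antonym_rest_length=4 * math.sqrt(2))
        assert node_energy((0, 0), [], [(0, 0)], cfg) == pytest.approx(16.0)

    def test_two_synonyms_closed_form(self):
        assert node_energy((0, 0), [(2, 0), (-2, 0)], [], CFG) == pytest.approx(4.0)

    def test_zero_iff_relaxed(self):
        cfg = replace(CFG, antonym_rest_length=2.0)
        assert node_energy((2, 2), [(2, 2)], [(-2, -2)], cfg) == 0.0
        assert node_energy((2, 2), [(2, 2)], [(1, 2)], cfg) > 0.0

    def test_non_finite_position_rejected(self):
        with pytest.raises(ValidationError):
            node_energy((float("nan"), 0), [(0, 0)], [], CFG)

    def test_source_weights_scale_energy(self):
        e1 = node_energy((0, 0), [(1, 0)], [], CFG, syn_weights=[1.0])
        e2 = node_energy((0, 0), [(1, 0)], [], CFG, syn_weights=[2.0])
        assert e2 == pytest.approx(2 * e1)


class TestEquilibriumPosition:
    def test_centroid_of_two_synonyms(self):
        assert equilibrium_position([(2, 0), (0, 2)], [], CFG) == (1.0, 1.0)

    def test_single_synonym(self):
        assert equilibrium_position([(-2, 1)], [], CFG) == (-2.0, 1.0)

    def test_weighted_centroid_uses_source_counts(self):
        p = equilibrium_position([(0, 0), (2, 0)], [], CFG,
                                 syn_weights=[1.0, 3.0])
        assert p == (1.5, 0.0)

    def test_no_neighbours_is_an_error(self):
        with pytest.raises(ValidationError):
            equilibrium_position([], [], CFG)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_dense_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        syn = rng.uniform(-2, 2, size=(rng.integers(1, 4), 2))
        ant = rng.uniform(-2, 2, size=(rng.integers(0, 3), 2))
        p = equilibrium_position(syn, ant, CFG, initial_guess=(0.0, 0.0))
        q, e_grid = grid_search_equilibrium(syn, ant, CFG)
        assert math.dist(p, q) <= 0.01
        assert node_energy(p, syn, ant, CFG) <= e_grid + 1e-9

    def test_result_never_worse_than_initial_guess(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            syn = rng.uniform(-2, 2, size=(2, 2))
            ant = rng.uniform(-2, 2, size=(2, 2))
            guess = tuple(rng.uniform(-2, 2, size=2))
            p = equilibrium_position(syn, ant, CFG, initial_guess=guess)
            assert (node_energy(p, syn, ant, CFG)
                    <= node_energy(guess, syn, ant, CFG) + 1e-9)


def _chain_fixture():
    lx = Lexicon([_adj("aa", 2.0, 0.0, anchor=True), _adj("bb"), _adj("cc")])
    g = ThesaurusGraph()
    g.add_edge(("aa", "adjective"), ("bb", "adjective"), "synonym")
    g.add_edge(("bb", "adjective"), ("cc", "adjective"), "synonym")
    return lx, g


class TestInitialPass:
    def test_propagates_down_a_chain(self):
        lx, g = _chain_fixture()
        out, state = initial_pass(lx, g)
        assert out[("bb", "adjective")].position == (2.0, 0.0)
        assert out[("cc", "adjective")].position == (2.0, 0.0)
        assert not state.unplaced

    def test_isolated_word_reported_unset(self):
        lx, g = _chain_fixture()
        lx.add(_adj("zz"))
        out, state = initial_pass(lx, g)
        assert not out[("zz", "adjective")].scored
        assert state.unplaced == [("zz", "adjective")]

    def test_star_placed_at_anchor_in_one_level(self):
        lx = Lexicon([_adj("hub", -1.0, 1.0, anchor=True)]
                     + [_adj(f"s{i}") for i in range(4)])
        g = ThesaurusGraph()
        for i in range(4):
            g.add_edge(("hub", "adjective"), (f"s{i}", "adjective"), "synonym")
        out, state = initial_pass(lx, g)
        for i in range(4):
            assert out[(f"s{i}", "adjective")].position == (-1.0, 1.0)
        assert state.placed_per_threshold == {100: 4}

    def test_no_anchors_cannot_bootstrap(self):
        lx = Lexicon([_adj("aa"), _adj("bb")])
        g = ThesaurusGraph()
        g.add_edge(("aa", "adjective"), ("bb", "adjective"), "synonym")
        with pytest.raises(BootstrapError):
            initial_pass(lx, g)

    def test_placed_words_carry_propagated_provenance(self):
        lx, g = _chain_fixture()
        out, _ = initial_pass(lx, g)
        assert out[("bb", "adjective")].provenance == "propagated"
        assert out[("aa", "adjective")].provenance == "unset"


class TestRelaxationSweep:
    def test_fixed_point_has_negligible_displacement(self):
        lx, g = _chain_fixture()
        out, _ = initial_pass(lx, g)
        _, disp = relaxation_sweep(out, g)
        assert disp < CFG.displacement_tolerance

    def test_two_mutual_synonyms_coalesce_sequentially(self):
        # 'aa' is visited first and moves onto 'bb'; 'bb' then stays
        lx = Lexicon([_adj("aa", 0.0, 0.0), _adj("bb", 2.0, 0.0)])
        g = ThesaurusGraph()
        g.add_edge(("aa", "adjective"), ("bb", "adjective"), "synonym")
        out, disp = relaxation_sweep(lx, g)
        assert out[("aa", "adjective")].position == (2.0, 0.0)
        assert out[("bb", "adjective")].position == (2.0, 0.0)
        assert disp == pytest.approx(2.0)

    def test_anchor_position_bit_identical(self):
        lx = Lexicon([_adj("aa", 1.25, -0.75, anchor=True),
                      _adj("bb", -2.0, 2.0)])
        g = ThesaurusGraph()
        g.add_edge(("aa", "adjective"), ("bb", "adjective"), "synonym")
        out, _ = relaxation_sweep(lx, g)
        assert out[("aa", "adjective")].position == (1.25, -0.75)
        assert out[("bb", "adjective")].position == (1.25, -0.75)


class TestPropagate:
    def test_fully_anchored_lexicon_is_a_fixed_point(self):
        lx = Lexicon([_adj("aa", 1.0, 1.0, anchor=True),
                      _adj("bb", -1.0, -1.0, anchor=True)])
        g = ThesaurusGraph()
        g.add_edge(("aa", "adjective"), ("bb", "adjective"), "antonym")
        out, state = propagate(lx, g)
        assert state.converged and state.sweeps == 1
        assert state.max_displacements == [0.0]
        assert out[("aa", "adjective")].position == (1.0, 1.0)

    def test_anchors_immutable_and_energy_monotone_on_synthetic_run(self):
        params = SynthParams(n_words=80, anchor_fraction=0.25,
                             position_distribution="cells", edge_noise=0.05,
                             seed=3)
        syn = generate_lexicon(params)
        graph = generate_graph(syn, params)
        before = {e.key: e.position for e in syn.lexicon if e.anchor}
        out, state = propagate(syn.lexicon, graph)
        for k, pos in before.items():
            assert out[k].position == pos        # bit-identical
            assert out[k].anchor
        diffs = np.diff(state.energies)
        assert np.all(diffs <= 1e-9)

    def test_reflection_equivariance(self):
        params = SynthParams(n_words=40, anchor_fraction=0.3,
                             position_distribution="uniform", edge_noise=0.0,
                             seed=11)
        syn = generate_lexicon(params)
        graph = generate_graph(syn, params)
        out, _ = propagate(syn.lexicon, graph)

        mirrored = Lexicon()
        for e in syn.lexicon:
            if e.scored:
                mirrored.add(WordEntry(e.lemma, e.pos, e.domain,
                                       -e.affiliation, -e.dominance,
                                       anchor=e.anchor, provenance=e.provenance))
            else:
                mirrored.add(e)
        out_m, _ = propagate(mirrored, graph)
        for e in out:
            if not e.scored:
                continue
            m = out_m[e.key]
            assert m.affiliation == pytest.approx(-e.affiliation, abs=1e-6)
            assert m.dominance == pytest.approx(-e.dominance, abs=1e-6)

    def test_synonym_only_converges_to_centroid_fixed_point(self):
        # k_ant = 0 reduces propagation to a harmonic (Laplacian) interpolation
        params = SynthParams(n_words=16, anchor_fraction=0.4,
                             position_distribution="uniform", edge_noise=0.0,
                             antonym_edge_fraction=0.0, mean_degree=4, seed=5)
        syn = generate_lexicon(params)
        graph = generate_graph(syn, params)
        cfg = replace(CFG, k_ant=0.0, displacement_tolerance=1e-8,
                      max_sweeps=2000)
        out, state = propagate(syn.lexicon, graph, cfg)
        exact = centroid_fixed_point(out, graph)
        for e in out:
            if not e.scored or e.anchor:
                continue
            # exact solve only constrains words connected to anchors
            if e.key in state.unplaced:
                continue
            assert e.position == pytest.approx(exact[e.key], abs=1e-5)

    def test_nonconvergence_reports_warning_state(self):
        lx, g = _chain_fixture()
        lx.add(_adj("dd", -2.0, 0.0, anchor=True))
        g.add_edge(("cc", "adjective"), ("dd", "adjective"), "synonym")
        cfg = replace(CFG, max_sweeps=1, displacement_tolerance=1e-12)
        out, state = propagate(lx, g, cfg)
        assert not state.converged
        assert state.sweeps == 1
        assert out[("bb", "adjective")].scored

    def test_total_energy_matches_node_sums(self):
        lx = Lexicon([_adj("aa", 1.0, 0.0), _adj("bb", -1.0, 0.0)])
        g = ThesaurusGraph()
        g.add_edge(("aa", "adjective"), ("bb", "adjective"), "antonym",
                   sources=2)
        expected = 0.5 * 2.0 * (CFG.antonym_rest_length - 2.0) ** 2
        assert total_energy(lx, g, CFG) == pytest.approx(expected)
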