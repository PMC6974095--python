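"""Semi-supervised spring-network scoring of the word catalogue.

Every unscored word is placed at the position minimising its Hooke's-law
spring energy against its scored neighbours: synonym springs have rest
length zero and pull the word toward its synonyms; antonym springs have a
finite rest length (by default the atlas half-diagonal, 2*sqrt(2)) and push
the word away from its antonyms, exerting no force beyond the rest length.

The procedure mirrors a force-directed layout with pinned nodes:

1. bootstrap — starting from the anchor words, repeatedly place every
   still-unscored word whose fraction of already-scored neighbours meets a
   threshold that decreases from 100% in 1-point steps;
2. relaxation — sweep all non-anchor words in alphabetical order, moving
   each to its equilibrium against the current positions of its
   neighbours (Gauss-Seidel style), until no word moves more than a
   tolerance.

Per-word minimisation is projected gradient descent with backtracking,
run from a symmetric lattice of starts so the reported position is the
best of several basins; with synonyms only the closed-form weighted
centroid is used directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import BootstrapError, ValidationError
from .graph import ThesaurusGraph
from .grid import GRID_MAX, GRID_MIN, snap_to_cell
from .lexicon import Key, Lexicon, WordEntry

ATLAS_DIAGONAL = 4.0 * math.sqrt(2.0)

#: Default antonym rest length: the atlas half-diagonal, the typical
#: separation of archetypal antonym pairs (reflections through the origin,
#: distance 2|p| with |p| up to 2*sqrt(2)).  A rest length equal to the full
#: diagonal would leave every antonym pair under permanent compression and
#: push the whole layout outward; the half-diagonal leaves a true reflected
#: configuration force-free while still repelling co-located antonyms.
ANTONYM_REST_LENGTH = 2.0 * math.sqrt(2.0)


@dataclass(frozen=True)
class SpringConfig:
    """Tunable parameters of the spring scorer.

    Stiffnesses are per unit source weight: an edge listed by both
    reference thesauri (sources=2) is twice as stiff as a single-source
    edge unless ``weight_by_sources`` is off.
    """

    k_syn: float = 1.0
    k_ant: float = 1.0
    antonym_rest_length: float = ANTONYM_REST_LENGTH
    threshold_start: int = 100          # percent
    threshold_step: int = 1             # percentage points
    displacement_tolerance: float = 1e-3
    max_sweeps: int = 100
    inner_solver_tolerance: float = 1e-6
    clamp_to_atlas: bool = True
    weight_by_sources: bool = True

    def __post_init__(self) -> None:
        if self.k_syn < 0 or self.k_ant < 0:
            raise ValidationError("spring stiffnesses must be non-negative")
        if self.antonym_rest_length <= 0:
            raise ValidationError("antonym rest length must be positive")
        if self.threshold_step < 1:
            raise ValidationError("threshold schedule must reach 0: step >= 1")
        if self.displacement_tolerance <= 0 or self.inner_solver_tolerance <= 0:
            raise ValidationError("tolerances must be positive")
        if self.max_sweeps < 1:
            raise ValidationError("max_sweeps must be positive")


@dataclass
class PropagationState:
    """Diagnostics of a propagation run."""

    sweeps: int = 0
    converged: bool = False
    max_displacements: list[float] = field(default_factory=list)
    energies: list[float] = field(default_factory=list)
    placed_per_threshold: dict[int, int] = field(default_factory=dict)
    unplaced: list[Key] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def _as_points(neighbors) -> np.ndarray:
    return np.asarray(list(neighbors), dtype=float).reshape(-1, 2)


def node_energy(position, syn_neighbors, ant_neighbors,
                config: SpringConfig = SpringConfig(),
                syn_weights=None, ant_weights=None) -> float:
    """Spring energy of one word at ``position``.

    E = sum_syn 1/2 k_syn w d^2  +  sum_ant 1/2 k_ant w max(0, L0 - d)^2

    with d the Euclidean distance to each neighbour and L0 the antonym
    rest length.  Zero iff the word coincides with all its synonyms and is
    at least L0 from all its antonyms.
    """
    p = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValidationError("position must be finite")
    syn = _as_points(syn_neighbors)
    ant = _as_points(ant_neighbors)
    sw = np.ones(len(syn)) if syn_weights is None else np.asarray(syn_weights, float)
    aw = np.ones(len(ant)) if ant_weights is None else np.asarray(ant_weights, float)
    e = 0.0
    if len(syn):
        d2 = ((p - syn) ** 2).sum(axis=1)
        e += 0.5 * config.k_syn * float((sw * d2).sum())
    if len(ant):
        d = np.sqrt(((p - ant) ** 2).sum(axis=1))
        pen = np.maximum(config.antonym_rest_length - d, 0.0)
        e += 0.5 * config.k_ant * float((aw * pen**2).sum())
    return e


def _energy_grad(P: np.ndarray, syn: np.ndarray, sw: np.ndarray,
                 ant: np.ndarray, aw: np.ndarray,
                 config: SpringConfig) -> tuple[np.ndarray, np.ndarray]:
    """Energy and gradient for a batch of candidate positions P (S, 2)."""
    S = len(P)
    E = np.zeros(S)
    G = np.zeros((S, 2))
    if len(syn):
        diff = P[:, None, :] - syn[None, :, :]          # (S, N, 2)
        d2 = (diff ** 2).sum(axis=2)
        E += 0.5 * config.k_syn * (sw * d2).sum(axis=1)
        G += config.k_syn * (sw[None, :, None] * diff).sum(axis=1)
    if len(ant):
        diff = P[:, None, :] - ant[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
        pen = np.maximum(config.antonym_rest_length - d, 0.0)
        E += 0.5 * config.k_ant * (aw * pen**2).sum(axis=1)
        # dE/dp = -k w pen * (p - q)/d ; zero (symmetric saddle) at d == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            coef = np.where(d > 0, -config.k_ant * aw * pen / d, 0.0)
        G += (coef[:, :, None] * diff).sum(axis=1)
    return E, G


# lattice of descent starts: symmetric under reflection through the origin,
# so the solver commutes with negating all inputs
_START_LATTICE = np.array([(a, d) for a in (-2.0, -1.0, 0.0, 1.0, 2.0)
                           for d in (-2.0, -1.0, 0.0, 1.0, 2.0)])


def equilibrium_position(syn_neighbors, ant_neighbors,
                         config: SpringConfig = SpringConfig(),
                         initial_guess=(0.0, 0.0),
                         syn_weights=None, ant_weights=None,
                         multistart: bool = True) -> tuple[float, float]:
    """Position minimising :func:`node_energy` against fixed neighbours.

    With synonym springs only the minimiser is the weighted centroid of
    the synonym neighbours, returned exactly.  Otherwise projected
    gradient descent with backtracking runs until the gradient norm falls
    below the inner solver tolerance.  With ``multistart`` (the default) a
    reflection-symmetric lattice of extra starts is used and the lowest
    energy wins; near-ties break toward the initial guess, so a word on a
    flat zero-force plateau stays where it is.  The result never has
    higher energy than the initial guess.
    """
    syn = _as_points(syn_neighbors)
    ant = _as_points(ant_neighbors)
    if len(syn) + len(ant) == 0:
        raise ValidationError("equilibrium undefined without neighbours")
    sw = np.ones(len(syn)) if syn_weights is None else np.asarray(syn_weights, float)
    aw = np.ones(len(ant)) if ant_weights is None else np.asarray(ant_weights, float)

    if len(ant) == 0 or config.k_ant == 0.0:
        if len(syn) == 0 or config.k_syn == 0.0 or sw.sum() == 0.0:
            raise ValidationError("equilibrium undefined: no active springs")
        c = (sw[:, None] * syn).sum(axis=0) / sw.sum()
        if config.clamp_to_atlas:
            c = np.clip(c, GRID_MIN, GRID_MAX)
        return (float(c[0]), float(c[1]))

    guess = np.asarray(initial_guess, dtype=float).reshape(1, 2)
    starts = [guess]
    if multistart:
        if len(syn) and sw.sum() > 0:
            starts.append(((sw[:, None] * syn).sum(axis=0) / sw.sum()).reshape(1, 2))
        starts.append(_START_LATTICE)
    P = np.clip(np.concatenate(starts, axis=0), GRID_MIN, GRID_MAX)

    E, G = _energy_grad(P, syn, sw, ant, aw, config)
    # near-Newton step: the synonym part of the Hessian is (sum k w) * I
    stiffness = config.k_syn * sw.sum() + config.k_ant * aw.sum()
    eta = np.full(len(P), 1.0 / max(stiffness, 1e-12))
    tol2 = config.inner_solver_tolerance ** 2

    for _ in range(120):
        gn2 = (G ** 2).sum(axis=1)
        active = gn2 > tol2
        if not active.any():
            break
        moved = False
        for _bt in range(25):
            P_try = P - eta[:, None] * G
            if config.clamp_to_atlas:
                P_try = np.clip(P_try, GRID_MIN, GRID_MAX)
            E_try, G_try = _energy_grad(P_try, syn, sw, ant, aw, config)
            ok = active & (E_try <= E - 1e-12)
            # clamped coordinates can leave the gradient finite at the
            # boundary minimum: treat a vanishing step as converged too
            stuck = active & (((P_try - P) ** 2).sum(axis=1) < 1e-24)
            if ok.any():
                upd = ok & ~stuck
                P[upd] = P_try[upd]
                E[upd] = E_try[upd]
                G[upd] = G_try[upd]
                eta[upd] *= 1.25
                moved = True
            shrink = active & ~ok & ~stuck
            if not shrink.any():
                break
            eta[shrink] *= 0.5
            active = shrink
        if not moved:
            break

    # lowest energy wins; near-equal energies break toward the guess
    e_min = float(E.min())
    tied = np.flatnonzero(E <= e_min + 1e-9)
    d_guess = ((P[tied] - guess) ** 2).sum(axis=1)
    p = P[tied[int(np.argmin(d_guess))]]
    if config.clamp_to_atlas:
        p = np.clip(p, GRID_MIN, GRID_MAX)
    return (float(p[0]), float(p[1]))


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _split_neighbors(key: Key, graph: ThesaurusGraph, positions: dict[Key, tuple],
                     config: SpringConfig):
    """Scored neighbours of ``key`` split by relation, with source weights."""
    syn_p, syn_w, ant_p, ant_w = [], [], [], []
    for nbr, relation, sources in graph.neighbors(key):
        pos = positions.get(nbr)
        if pos is None:
            continue
        w = float(sources) if config.weight_by_sources else 1.0
        if relation == "synonym":
            syn_p.append(pos)
            syn_w.append(w)
        else:
            ant_p.append(pos)
            ant_w.append(w)
    return syn_p, syn_w, ant_p, ant_w


def _has_active_springs(syn_p, ant_p, config: SpringConfig) -> bool:
    return bool((syn_p and config.k_syn > 0) or (ant_p and config.k_ant > 0))


def _initial_guess(syn_p, syn_w, ant_p, ant_w) -> tuple[float, float]:
    if syn_p:
        w = np.asarray(syn_w)
        c = (w[:, None] * np.asarray(syn_p)).sum(axis=0) / w.sum()
    elif ant_p:
        w = np.asarray(ant_w)
        c = -(w[:, None] * np.asarray(ant_p)).sum(axis=0) / w.sum()
    else:
        c = np.zeros(2)
    return tuple(np.clip(c, GRID_MIN, GRID_MAX))


def total_energy(lexicon: Lexicon, graph: ThesaurusGraph,
                 config: SpringConfig = SpringConfig()) -> float:
    """Total spring energy over edges whose both endpoints are scored."""
    e = 0.0
    for key_a, key_b, relation, sources in graph.edges():
        ea, eb = lexicon.get(key_a), lexicon.get(key_b)
        if ea is None or eb is None or not (ea.scored and eb.scored):
            continue
        w = float(sources) if config.weight_by_sources else 1.0
        d = math.dist(ea.position, eb.position)
        if relation == "synonym":
            e += 0.5 * config.k_syn * w * d * d
        else:
            pen = max(config.antonym_rest_length - d, 0.0)
            e += 0.5 * config.k_ant * w * pen * pen
    return e


def initial_pass(lexicon: Lexicon, graph: ThesaurusGraph,
                 config: SpringConfig = SpringConfig()
                 ) -> tuple[Lexicon, PropagationState]:
    """Bootstrap scoring with the decreasing-threshold schedule.

    The threshold starts at 100% and drops by ``threshold_step`` points;
    at each level, any unscored word with at least one scored neighbour
    and a scored-neighbour fraction meeting the threshold is placed (in
    alphabetical order, cascading within the level) at its equilibrium
    against its scored neighbours.  Words with no path to an anchor stay
    unset and are reported.
    """
    lex = lexicon.copy()
    if not any(e.scored for e in lex):
        raise BootstrapError("cannot bootstrap: no scored anchors in the lexicon")
    state = PropagationState()
    positions: dict[Key, tuple[float, float]] = {
        e.key: e.position for e in lex if e.scored}

    unscored = set(lex.unscored_keys())
    threshold = config.threshold_start
    while threshold >= 0:
        placed_here = 0
        while True:
            placed_round = []
            for key in sorted(unscored):
                nbrs = graph.neighbors(key)
                if not nbrs:
                    continue
                n_scored = sum(1 for nbr, _, _ in nbrs if nbr in positions)
                if n_scored == 0 or 100.0 * n_scored / len(nbrs) < threshold:
                    continue
                syn_p, syn_w, ant_p, ant_w = _split_neighbors(
                    key, graph, positions, config)
                if not _has_active_springs(syn_p, ant_p, config):
                    continue
                pos = equilibrium_position(
                    syn_p, ant_p, config,
                    initial_guess=_initial_guess(syn_p, syn_w, ant_p, ant_w),
                    syn_weights=syn_w, ant_weights=ant_w)
                positions[key] = pos
                entry = lex[key]
                lex.replace_entry(WordEntry(
                    lemma=entry.lemma, pos=entry.pos, domain=entry.domain,
                    affiliation=pos[0], dominance=pos[1],
                    anchor=False, provenance="propagated"))
                placed_round.append(key)
            if not placed_round:
                break
            unscored.difference_update(placed_round)
            placed_here += len(placed_round)
        if placed_here:
            state.placed_per_threshold[threshold] = placed_here
        if not unscored:
            break
        threshold -= config.threshold_step
    state.unplaced = sorted(unscored)
    return lex, state


def relaxation_sweep(lexicon: Lexicon, graph: ThesaurusGraph,
                     config: SpringConfig = SpringConfig()
                     ) -> tuple[Lexicon, float]:
    """One Gauss-Seidel sweep: every scored non-anchor word, visited in
    alphabetical order of (lemma, pos), moves to its equilibrium against
    the *current* positions of its neighbours.  Anchors never move.
    Returns the updated lexicon and the maximum single-word displacement.
    """
    lex = lexicon.copy()
    positions: dict[Key, tuple[float, float]] = {
        e.key: e.position for e in lex if e.scored}
    max_disp = 0.0
    for key in lex.sorted_keys():
        entry = lex[key]
        if entry.anchor or not entry.scored:
            continue
        syn_p, syn_w, ant_p, ant_w = _split_neighbors(key, graph, positions, config)
        if not _has_active_springs(syn_p, ant_p, config):
            continue
        old = positions[key]
        # local refinement from the current position: Gauss-Seidel descent
        new = equilibrium_position(syn_p, ant_p, config, initial_guess=old,
                                   syn_weights=syn_w, ant_weights=ant_w,
                                   multistart=False)
        disp = math.dist(old, new)
        if disp > max_disp:
            max_disp = disp
        positions[key] = new
        lex.replace_entry(WordEntry(
            lemma=entry.lemma, pos=entry.pos, domain=entry.domain,
            affiliation=new[0], dominance=new[1],
            anchor=False,
            provenance="propagated" if disp > 0 else entry.provenance))
    return lex, max_disp


def propagate(lexicon: Lexicon, graph: ThesaurusGraph,
              config: SpringConfig = SpringConfig()
              ) -> tuple[Lexicon, PropagationState]:
    """Full scoring run: bootstrap, then relaxation sweeps to equilibrium.

    Sweeps stop once the largest single-word displacement falls below the
    displacement tolerance, or after ``max_sweeps`` (in which case the
    state carries ``converged=False`` and positions are still returned).
    Anchors are bit-identical before and after; the per-sweep total energy
    trace is non-increasing.
    """
    lex, state = initial_pass(lexicon, graph, config)
    state.energies.append(total_energy(lex, graph, config))
    for sweep in range(1, config.max_sweeps + 1):
        lex, max_disp = relaxation_sweep(lex, graph, config)
        state.sweeps = sweep
        state.max_displacements.append(max_disp)
        state.energies.append(total_energy(lex, graph, config))
        if max_disp < config.displacement_tolerance:
            state.converged = True
            break
    return lex, state
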