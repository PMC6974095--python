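"""Dipole questionnaire design over the 24 non-centre atlas cells.

A 12-item forced-choice test pairs up all 24 non-centre cells; each item
offers an antonym pair drawn from the two cells of a pair, plus an n/a
option.  The search space is the set of perfect matchings of the cells
(23!! ~ 3.2e11 for the full atlas).  An exact branch-and-bound finds the
maximum mean pair distance and *all* matchings attaining it; a brute-force
enumerator serves as an oracle at small sizes, and uniform sampling of
matchings supports distribution studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .constructs import (Construct, EfficacyMeasures, map_construct, measures)
from .errors import InsufficiencyError, ValidationError
from .grid import NON_CENTRE_CELLS, AtlasCell
from .lexicon import Key, Lexicon

Metric = Callable[[AtlasCell, AtlasCell], float]

TIE_TOLERANCE = 1e-9


def euclidean(a: AtlasCell, b: AtlasCell) -> float:
    return a.distance(b)


def min_questions(n_cells: int, cells_per_item: int) -> int:
    """Minimum number of items needed to cover ``n_cells`` when each item
    compares ``cells_per_item`` cells at once (the covering bound)."""
    if n_cells < 1 or cells_per_item < 1:
        raise ValidationError("cell counts must be positive")
    return -(-n_cells // cells_per_item)


def _canonical(pairs: Iterable[tuple[AtlasCell, AtlasCell]]
               ) -> tuple[tuple[AtlasCell, AtlasCell], ...]:
    ordered = [tuple(sorted(p)) for p in pairs]
    return tuple(sorted(ordered))


@dataclass(frozen=True)
class DipolePairing:
    """A perfect matching of cells into dipole pairs, with its mean distance."""

    pairs: tuple[tuple[AtlasCell, AtlasCell], ...]
    mean_distance: float

    def __post_init__(self) -> None:
        seen: set[AtlasCell] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"cell {a} paired with itself")
            for c in (a, b):
                if c.is_centre:
                    raise ValidationError("centre cell cannot join a dipole")
                if c in seen:
                    raise ValidationError(f"cell {c} appears in two pairs")
                seen.add(c)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[AtlasCell, AtlasCell]],
                   metric: Metric = euclidean) -> "DipolePairing":
        canon = _canonical(pairs)
        mean = float(np.mean([metric(a, b) for a, b in canon])) if canon else 0.0
        return cls(pairs=canon, mean_distance=mean)

    @property
    def cells(self) -> set[AtlasCell]:
        return {c for p in self.pairs for c in p}


def reflection_pairing(metric: Metric = euclidean) -> DipolePairing:
    """The matching that joins every non-centre cell to its reflection
    through the origin (always among the maximizers for the atlas)."""
    from .grid import reflection_pairs
    return DipolePairing.from_pairs(reflection_pairs(), metric)


@dataclass
class MatchingResult:
    """Exact optimum of the matching search, with every tie retained."""

    max_mean_distance: float
    maximizers: list[DipolePairing]
    nodes_explored: int = 0

    @property
    def maximizer_count(self) -> int:
        return len(self.maximizers)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_matchings_bruteforce(cells: Sequence[AtlasCell],
                                   metric: Metric = euclidean
                                   ) -> list[tuple[tuple[tuple[AtlasCell, AtlasCell], ...], float]]:
    """Exhaustively enumerate all (n-1)!! perfect matchings with their mean
    pair distances.  Oracle-scale only: at most 12 cells."""
    cells = list(cells)
    if len(cells) % 2:
        raise ValidationError(f"odd number of cells ({len(cells)}): no perfect matching")
    if len(cells) > 12:
        raise ValidationError("brute-force enumeration limited to 12 cells")
    results: list[tuple[tuple[tuple[AtlasCell, AtlasCell], ...], float]] = []

    def recurse(free: list[AtlasCell], acc: list[tuple[AtlasCell, AtlasCell]]) -> None:
        if not free:
            canon = _canonical(acc)
            mean = float(np.mean([metric(a, b) for a, b in canon]))
            results.append((canon, mean))
            return
        first = free[0]
        for i in range(1, len(free)):
            partner = free[i]
            rest = free[1:i] + free[i + 1:]
            acc.append((first, partner))
            recurse(rest, acc)
            acc.pop()

    if cells:
        recurse(sorted(cells), [])
    return results


# ---------------------------------------------------------------------------
# Exact search
# ---------------------------------------------------------------------------

def max_avg_distance_matching(cells: Sequence[AtlasCell] = NON_CENTRE_CELLS,
                              metric: Metric = euclidean) -> MatchingResult:
    """Find the maximum mean pair distance over all perfect matchings of
    ``cells`` and every matching attaining it (ties kept to 1e-9).

    Branch-and-bound: branch on the lowest-indexed free cell; the bound is
    the current sum plus half the sum, over free cells, of each cell's best
    remaining pair distance (admissible, so no maximizer is lost).
    """
    cells = list(cells)
    n = len(cells)
    if n % 2:
        raise ValidationError(f"odd number of cells ({n}): no perfect matching")
    if n == 0:
        return MatchingResult(max_mean_distance=0.0, maximizers=[])
    Dm = np.array([[metric(a, b) for b in cells] for a in cells], dtype=float)
    # visiting cells in descending eccentricity tightens the bound early
    order = sorted(range(n), key=lambda i: -Dm[i].max())
    Dm = Dm[np.ix_(order, order)]
    ordered_cells = [cells[i] for i in order]
    D = [[float(v) for v in row] for row in Dm]          # python floats: fast scalar ops
    # partner visit order per cell: most distant first, for good incumbents early
    partner_order = [sorted((j for j in range(n) if j != i),
                            key=lambda j: -D[i][j]) for i in range(n)]

    n_pairs = n // 2
    best_sum = -math.inf
    best: list[tuple[tuple[int, int], ...]] = []
    nodes = 0

    free = [True] * n
    acc: list[tuple[int, int]] = []
    # bestd[k]: distance from k to its farthest free partner (maintained
    # incrementally); half their sum over free cells is the admissible bound
    bestd = [0.0] * n
    bestp = [-1] * n
    for i in range(n):
        j = max((j for j in range(n) if j != i), key=lambda j: D[i][j])
        bestd[i], bestp[i] = D[i][j], j
    bound_sum = sum(bestd)  # = 2 * (upper bound on the remaining pair sum)

    def assignment_bound() -> float:
        # relaxed maximum-weight assignment on the free cells: every perfect
        # matching is half of a symmetric self-avoiding assignment, so half
        # the optimal assignment weight is an admissible (and tight) bound
        idx = np.flatnonzero(free)
        if idx.size == 0:
            return 0.0
        sub = Dm[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, -1e9)
        rows, cols = linear_sum_assignment(sub, maximize=True)
        return 0.5 * float(sub[rows, cols].sum())

    def recurse(cur_sum: float) -> None:
        nonlocal best_sum, nodes, bound_sum
        nodes += 1
        if len(acc) == n_pairs:
            if cur_sum > best_sum + TIE_TOLERANCE:
                best_sum = cur_sum
                best.clear()
                best.append(tuple(acc))
            elif cur_sum >= best_sum - TIE_TOLERANCE:
                best.append(tuple(acc))
            return
        i = free.index(True)
        for j in partner_order[i]:
            if not free[j]:
                continue
            new_sum = cur_sum + D[i][j]
            free[i] = free[j] = False
            # repair bestd for free cells whose best partner was i or j
            touched: list[tuple[int, float, int]] = []
            delta = bestd[i] + bestd[j]
            Di, Dj = D[i], D[j]
            for k in range(n):
                if free[k] and (bestp[k] == i or bestp[k] == j):
                    touched.append((k, bestd[k], bestp[k]))
                    Dk = D[k]
                    bd, bp = -1.0, -1
                    for m in range(n):
                        if free[m] and m != k and Dk[m] > bd:
                            bd, bp = Dk[m], m
                    delta += bestd[k] - bd
                    bestd[k], bestp[k] = bd, bp
            bound_sum -= delta
            if new_sum + 0.5 * bound_sum >= best_sum - TIE_TOLERANCE and \
                    new_sum + assignment_bound() >= best_sum - TIE_TOLERANCE:
                acc.append((i, j))
                recurse(new_sum)
                acc.pop()
            bound_sum += delta
            for k, bd, bp in touched:
                bestd[k], bestp[k] = bd, bp
            free[i] = free[j] = True

    recurse(0.0)

    maximizers = [
        DipolePairing.from_pairs(
            [(ordered_cells[i], ordered_cells[j]) for i, j in sol], metric)
        for sol in best
    ]
    # canonical, deterministic presentation order
    maximizers.sort(key=lambda m: m.pairs)
    return MatchingResult(max_mean_distance=best_sum / n_pairs,
                          maximizers=maximizers, nodes_explored=nodes)


# ---------------------------------------------------------------------------
# Uniform sampling
# ---------------------------------------------------------------------------

@dataclass
class SampleSummary:
    """Distribution summary of mean pair distances over sampled matchings."""

    n_samples: int
    mean: float
    max: float
    min: float
    quantiles: dict[float, float]
    counts: dict[tuple[tuple[AtlasCell, AtlasCell], ...], int] | None = None


def sample_matchings(cells: Sequence[AtlasCell], n_samples: int, seed: int,
                     metric: Metric = euclidean,
                     quantile_levels: Sequence[float] = (0.5, 0.9, 0.99, 0.999),
                     return_counts: bool = False) -> SampleSummary:
    """Draw uniform random perfect matchings and summarise their mean pair
    distances.  Reproducible for a fixed seed; the sample maximum can never
    exceed the exact optimum."""
    cells = list(cells)
    n = len(cells)
    if n % 2:
        raise ValidationError(f"odd number of cells ({n}): no perfect matching")
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    D = np.array([[metric(a, b) for b in cells] for a in cells], dtype=float)
    # a uniformly random permutation paired off consecutively is a uniform
    # perfect matching (each matching has the same number of orderings)
    perms = np.tile(np.arange(n), (n_samples, 1))
    perms = rng.permuted(perms, axis=1)
    a_idx = perms[:, 0::2]
    b_idx = perms[:, 1::2]
    means = D[a_idx, b_idx].mean(axis=1)
    counts = None
    if return_counts:
        counts = {}
        for row_a, row_b in zip(a_idx, b_idx):
            canon = _canonical((cells[i], cells[j]) for i, j in zip(row_a, row_b))
            counts[canon] = counts.get(canon, 0) + 1
    qs = {float(q): float(np.quantile(means, q)) for q in quantile_levels}
    return SampleSummary(n_samples=n_samples, mean=float(means.mean()),
                         max=float(means.max()), min=float(means.min()),
                         quantiles=qs, counts=counts)


# ---------------------------------------------------------------------------
# Questionnaire assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuestionnaireItem:
    """One dipole item: a forced choice between two antonyms (plus n/a)."""

    negative: Key            # word in the lexicographically smaller cell
    positive: Key
    cells: tuple[AtlasCell, AtlasCell]


@dataclass
class Questionnaire:
    """A dipole questionnaire; 12 items cover all 24 non-centre cells."""

    items: list[QuestionnaireItem]

    def cell_pairs(self) -> list[tuple[AtlasCell, AtlasCell]]:
        return [it.cells for it in self.items]

    def to_markdown(self) -> str:
        lines = ["| ID | Word | | | | Antonym | Cells |",
                 "|---|---|---|---|---|---|---|"]
        for i, it in enumerate(self.items, start=1):
            ca, cb = it.cells
            lines.append(
                f"| {i} | {it.negative[0]} | ☐ | n/a ☐ | ☐ | {it.positive[0]} "
                f"| {ca}—{cb} |")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {"items": [
            {"negative": {"lemma": it.negative[0], "pos": it.negative[1]},
             "positive": {"lemma": it.positive[0], "pos": it.positive[1]},
             "cells": [list(it.cells[0].as_tuple()), list(it.cells[1].as_tuple())]}
            for it in self.items]}


def select_question_words(pairing: DipolePairing,
                          antonym_pool: Sequence[tuple[Key, Key]],
                          lexicon: Lexicon) -> Questionnaire:
    """Pick one antonym word pair for every cell pair of a dipole pairing.

    Orientation is fixed: the word in the lexicographically smaller cell is
    listed first (the left-hand, 'negative' column of a printed test).  The
    deterministic choice is the lexicographically first eligible word pair.
    Fails atomically, naming the first cell pair no pool pair can cover.
    """
    by_cells: dict[tuple[AtlasCell, AtlasCell], list[tuple[Key, Key]]] = {}
    for key_a, key_b in antonym_pool:
        ea, eb = lexicon[key_a], lexicon[key_b]
        if not (ea.scored and eb.scored):
            raise ValidationError(
                f"pool pair {key_a}/{key_b} contains an unscored word")
        ca, cb = ea.cell, eb.cell
        if cb < ca:  # orient: smaller cell's word first
            ca, cb = cb, ca
            key_a, key_b = key_b, key_a
        by_cells.setdefault((ca, cb), []).append((key_a, key_b))

    items: list[QuestionnaireItem] = []
    for pair in pairing.pairs:
        eligible = by_cells.get(pair, [])
        if not eligible:
            raise InsufficiencyError(
                f"no antonym pair in the pool spans cells {pair[0]}—{pair[1]}",
                cell_pair=pair)
        neg, pos = min(eligible)
        items.append(QuestionnaireItem(negative=neg, positive=pos, cells=pair))
    return Questionnaire(items=items)


def questionnaire_construct(questionnaire: Questionnaire) -> Construct:
    """View a questionnaire as a construct: each item side is a single-word
    pole, each item a dipole between its two poles."""
    poles = []
    dipoles = []
    for i, it in enumerate(questionnaire.items):
        poles.append((f"item{i + 1}-negative", (it.negative,)))
        poles.append((f"item{i + 1}-positive", (it.positive,)))
        dipoles.append((2 * i, 2 * i + 1))
    return Construct(name="questionnaire", poles=tuple(poles),
                     dipoles=tuple(dipoles))


def test_measures(questionnaire: Questionnaire,
                  lexicon: Lexicon) -> EfficacyMeasures:
    """Efficacy-table row for a questionnaire (each side a single-word pole)."""
    construct = questionnaire_construct(questionnaire)
    return measures(map_construct(construct, lexicon))


# ---------------------------------------------------------------------------
# Response scoring
# ---------------------------------------------------------------------------

RESPONSE_VALUES = ("negative", "n/a", "positive")


@dataclass
class ResponseProfile:
    """A respondent's position estimate: the mean of the chosen words' cells.

    Not normed against any population; an exploratory summary only.
    """

    affiliation: float | None
    dominance: float | None
    n_answered: int
    cell_tallies: dict[AtlasCell, int] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.affiliation is not None


def score_responses(questionnaire: Questionnaire,
                    responses: Sequence[str]) -> ResponseProfile:
    """Score a filled questionnaire: each non-n/a choice contributes the
    chosen word's cell coordinates; the profile is their mean vector."""
    if len(responses) != len(questionnaire.items):
        raise ValidationError(
            f"expected {len(questionnaire.items)} responses, got {len(responses)}")
    tallies: dict[AtlasCell, int] = {}
    acc = np.zeros(2)
    n = 0
    for item, resp in zip(questionnaire.items, responses):
        if resp not in RESPONSE_VALUES:
            raise ValidationError(f"invalid response {resp!r}")
        if resp == "n/a":
            continue
        cell = item.cells[0] if resp == "negative" else item.cells[1]
        tallies[cell] = tallies.get(cell, 0) + 1
        acc += (cell.affiliation, cell.dominance)
        n += 1
    if n == 0:
        return ResponseProfile(affiliation=None, dominance=None,
                               n_answered=0, cell_tallies={})
    return ResponseProfile(affiliation=float(acc[0] / n),
                           dominance=float(acc[1] / n),
                           n_answered=n, cell_tallies=tallies)
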