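"""Synthetic lexicons and thesaurus graphs with planted ground truth.

The generator emulates the structure the spring scorer relies on: words
have true positions in the atlas square, synonym edges preferentially
join nearby words, antonym edges join words lying near each other's
reflection through the origin, a designated anchor subset carries known
scores, and a fraction of edges is rewired at random as noise.  It makes
no attempt to imitate English thesaurus degree distributions or polysemy;
it provides controlled recovery experiments, not realistic text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateParametersError, ValidationError
from .graph import ThesaurusGraph
from .grid import ALL_CELLS, AtlasCell, reflection_pairs, snap_to_cell
from .lexicon import DOMAIN_VALUES, POS_VALUES, Key, Lexicon, WordEntry

logger = logging.getLogger(__name__)

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]  # 65 syllables


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic world.

    ``synonym_radius`` and ``antonym_tolerance`` are in cell units; the
    defaults (0.8) let planted structure span adjacent cells, so recovery
    is feasible but not trivial.  ``edge_noise`` is the fraction of edges
    rewired to uniformly random endpoints after construction.
    """

    n_words: int = 200
    anchor_fraction: float = 0.2
    synonym_radius: float = 0.8
    antonym_tolerance: float = 0.8
    mean_degree: float = 6.0
    edge_noise: float = 0.05
    position_distribution: str = "uniform"     # "uniform" | "cells"
    cell_sigma: float = 0.0                    # spread of the cell-centre mixture
    antonym_edge_fraction: float = 0.15        # share of edges that are antonymic
    pool_pairs_per_cell: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise ValidationError("n_words must be positive")
        if not 0 < self.anchor_fraction <= 1:
            raise ValidationError("anchor_fraction must be in (0, 1]")
        if self.synonym_radius <= 0 or self.antonym_tolerance <= 0:
            raise ValidationError("radii must be positive")
        if self.mean_degree <= 0:
            raise ValidationError("mean_degree must be positive")
        if not 0 <= self.edge_noise < 1:
            raise ValidationError("edge_noise must be in [0, 1)")
        if self.position_distribution not in ("uniform", "cells"):
            raise ValidationError(
                f"unknown position distribution {self.position_distribution!r}")
        if self.cell_sigma < 0:
            raise ValidationError("cell_sigma must be non-negative")
        if not 0 <= self.antonym_edge_fraction < 1:
            raise ValidationError("antonym_edge_fraction must be in [0, 1)")


@dataclass
class SyntheticLexicon:
    """A generated catalogue: working lexicon (anchors scored, the rest
    unset) plus the planted true position of every word."""

    lexicon: Lexicon
    truth: dict[Key, tuple[float, float]]

    @property
    def anchor_keys(self) -> set[Key]:
        return {e.key for e in self.lexicon if e.anchor}

    def truth_lexicon(self) -> Lexicon:
        """The catalogue with every word at its true position."""
        lx = Lexicon()
        for e in self.lexicon:
            a, d = self.truth[e.key]
            lx.add(WordEntry(lemma=e.lemma, pos=e.pos, domain=e.domain,
                             affiliation=a, dominance=d,
                             anchor=e.anchor, provenance="synthetic"))
        return lx


def _make_lemma(i: int) -> str:
    s = _SYLLABLES
    n = len(s)
    parts = [s[(i // (n * n)) % n], s[(i // n) % n], s[i % n]]
    return "".join(parts)


def generate_lexicon(params: SynthParams) -> SyntheticLexicon:
    """Generate ``n_words`` entries with planted true positions.

    Lemmas are pronounceable and unique; POS and domain are assigned
    round-robin.  Exactly ceil(anchor_fraction * n) entries are anchors
    with their working score equal to the truth; all other working scores
    are unset.  A pure function of the parameters (seed included).
    """
    n = params.n_words
    n_anchors = math.ceil(params.anchor_fraction * n)
    if n_anchors < 1:
        raise ValidationError("anchor_fraction * n_words must be at least 1")
    rng = np.random.default_rng(params.seed)
    if params.position_distribution == "uniform":
        pos = rng.uniform(-2.0, 2.0, size=(n, 2))
    else:
        # isotropic Gaussian mixture on the 25 cell centres, clipped to the
        # square; sigma = 0 degenerates to exact centres
        centres = np.array([c.as_tuple() for c in ALL_CELLS], dtype=float)
        pos = centres[rng.integers(0, len(centres), size=n)]
        if params.cell_sigma > 0:
            pos = np.clip(pos + rng.normal(0.0, params.cell_sigma, size=(n, 2)),
                          -2.0, 2.0)
    anchor_idx = set(rng.choice(n, size=n_anchors, replace=False).tolist())

    lx = Lexicon()
    truth: dict[Key, tuple[float, float]] = {}
    for i in range(n):
        lemma = _make_lemma(i)
        p = POS_VALUES[i % len(POS_VALUES)]
        dom = DOMAIN_VALUES[(i // len(POS_VALUES)) % len(DOMAIN_VALUES)]
        a, d = float(pos[i, 0]), float(pos[i, 1])
        truth[(lemma, p)] = (a, d)
        if i in anchor_idx:
            lx.add(WordEntry(lemma=lemma, pos=p, domain=dom,
                             affiliation=a, dominance=d,
                             anchor=True, provenance="synthetic"))
        else:
            lx.add(WordEntry(lemma=lemma, pos=p, domain=dom))
    return SyntheticLexicon(lexicon=lx, truth=truth)


def generate_graph(synthetic: SyntheticLexicon,
                   params: SynthParams) -> ThesaurusGraph:
    """Plant a typed edge structure over the true positions.

    Synonym edges are sampled among pairs within ``synonym_radius``;
    antonym edges among pairs where one word lies within
    ``antonym_tolerance`` of the other's reflection through the origin.
    Sampling targets ``mean_degree`` in expectation, then ``edge_noise``
    of the edges are rewired to uniform random endpoints (type kept).
    Source counts are 2 with probability 1/2, else 1.
    """
    keys = sorted(synthetic.truth)
    pts = np.array([synthetic.truth[k] for k in keys])
    n = len(keys)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    tree = cKDTree(pts)
    syn_cand = [(i, j) for i, j in tree.query_pairs(params.synonym_radius)]
    # antonym candidates: i within tolerance of -p_j  <=>  |p_i + p_j| <= tol
    rtree = cKDTree(-pts)
    ant_cand = []
    for i, js in enumerate(tree.query_ball_tree(rtree, params.antonym_tolerance)):
        for j in js:
            if i < j:
                ant_cand.append((i, j))
    if not syn_cand and not ant_cand:
        raise DegenerateParametersError(
            "no synonym or antonym candidates under the given radii")

    target_edges = params.mean_degree * n / 2.0
    ant_target = int(round(target_edges * params.antonym_edge_fraction))
    syn_target = int(round(target_edges)) - ant_target

    def sample(cand: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
        if not cand or k <= 0:
            return []
        k = min(k, len(cand))
        idx = rng.choice(len(cand), size=k, replace=False)
        return [cand[i] for i in sorted(idx.tolist())]

    edges: list[tuple[int, int, str]] = (
        [(i, j, "synonym") for i, j in sample(syn_cand, syn_target)]
        + [(i, j, "antonym") for i, j in sample(ant_cand, ant_target)])
    if not edges:
        raise DegenerateParametersError("edge sampling produced no edges")

    # noise: rewire a fraction of edges to uniformly random endpoints
    n_rewire = int(math.floor(params.edge_noise * len(edges)))
    if n_rewire:
        existing = {(i, j) for i, j, _ in edges}
        rewire_idx = rng.choice(len(edges), size=n_rewire, replace=False)
        for e_idx in sorted(rewire_idx.tolist()):
            rel = edges[e_idx][2]
            for _ in range(100):
                i, j = rng.integers(0, n, size=2).tolist()
                if i == j:
                    continue
                i, j = min(i, j), max(i, j)
                if (i, j) in existing:
                    continue
                existing.discard(edges[e_idx][:2])
                edges[e_idx] = (i, j, rel)
                existing.add((i, j))
                break

    graph = ThesaurusGraph()
    for k in keys:
        graph.add_node(k)
    sources = rng.integers(1, 3, size=len(edges))
    for (i, j, rel), src in zip(edges, sources.tolist()):
        graph.add_edge(keys[i], keys[j], relation=rel, sources=int(src))
    return graph


def generate_antonym_pool(synthetic: SyntheticLexicon,
                          params: SynthParams,
                          strict: bool = True) -> list[tuple[Key, Key]]:
    """Build an antonym-pair pool covering the 12 reflection cell pairs.

    Intended for lexicons drawn from the cell-centre mixture: for each
    reflection pair of cells, up to ``pool_pairs_per_cell`` word pairs are
    formed from words truly located in the two cells.  An uncoverable cell
    pair raises (strict) or is logged and skipped.
    """
    by_cell: dict[AtlasCell, list[Key]] = {}
    for key, (a, d) in synthetic.truth.items():
        by_cell.setdefault(snap_to_cell(a, d), []).append(key)
    pool: list[tuple[Key, Key]] = []
    for ca, cb in reflection_pairs():
        left = sorted(by_cell.get(ca, []))
        right = sorted(by_cell.get(cb, []))
        if not left or not right:
            msg = f"no words available to span cells {ca}—{cb}"
            if strict:
                raise DegenerateParametersError(msg)
            logger.warning("antonym pool: %s", msg)
            continue
        for k in range(min(params.pool_pairs_per_cell, len(left), len(right))):
            pool.append((left[k], right[k]))
    return pool


@dataclass
class RecoveryReport:
    """Recovery quality of estimated vs planted positions (non-anchors)."""

    rmse: float
    cell_accuracy: float
    n_words: int
    confusion: np.ndarray        # 25 x 25, true cell x estimated cell

    @staticmethod
    def cell_index(cell: AtlasCell) -> int:
        return (cell.affiliation + 2) * 5 + (cell.dominance + 2)


def recovery_report(true_positions: dict[Key, tuple[float, float]],
                    estimated_positions: dict[Key, tuple[float, float]],
                    anchor_keys: set[Key] = frozenset()) -> RecoveryReport:
    """RMSE and snapped-cell accuracy of the estimates, anchors excluded."""
    missing = set(true_positions) - set(estimated_positions)
    extra = set(estimated_positions) - set(true_positions)
    if missing or extra:
        raise ValidationError(
            f"key sets differ: missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}")
    keys = [k for k in sorted(true_positions) if k not in anchor_keys]
    if not keys:
        raise ValidationError("no non-anchor words to evaluate")
    t = np.array([true_positions[k] for k in keys])
    e = np.array([estimated_positions[k] for k in keys])
    rmse = float(np.sqrt(((t - e) ** 2).sum(axis=1).mean()))
    confusion = np.zeros((25, 25), dtype=int)
    hits = 0
    for (ta, td), (ea, ed) in zip(t, e):
        tc = snap_to_cell(ta, td)
        ec = snap_to_cell(ea, ed)
        confusion[RecoveryReport.cell_index(tc), RecoveryReport.cell_index(ec)] += 1
        hits += tc == ec
    return RecoveryReport(rmse=rmse, cell_accuracy=hits / len(keys),
                          n_words=len(keys), confusion=confusion)


def benchmark_params(seed: int = 7) -> SynthParams:
    """The frozen recovery benchmark: 200 words on cell centres, 20%
    anchors, mean degree 6, 5% edge noise."""
    return SynthParams(n_words=200, anchor_fraction=0.2,
                       position_distribution="cells", edge_noise=0.05,
                       seed=seed)
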