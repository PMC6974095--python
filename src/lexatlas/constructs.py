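"""Mapping word-list constructs onto the atlas and scoring their efficacy.

A construct (a personality scale, diagnostic category, social concept...)
is a named set of poles, each pole a word list; optional dipoles join
opposing poles.  Constructs are mapped to atlas positions through a scored
lexicon, visualised as Gaussian kernel densities over the square, and
compared through three efficacy measures:

* completeness — fraction of the 24 non-centre cells occupied by a pole's
  modal cell (or a dipole endpoint);
* diffusion — fraction of mapped words lying outside their pole's modal
  cell (lower is sharper);
* discrimination — mean distance between the two poles of each dipole
  (undefined without dipoles).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyPoleError, ValidationError
from .grid import CENTRE_CELL, AtlasCell, snap_to_cell
from .lexicon import Key, Lexicon

logger = logging.getLogger(__name__)

N_DESIGN_CELLS = 24  # the completeness denominator: all cells bar the centre


@dataclass(frozen=True)
class Construct:
    """A named construct: ordered poles of word keys, optional dipoles."""

    name: str
    poles: tuple[tuple[str, tuple[Key, ...]], ...]
    dipoles: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.poles:
            raise ValidationError(f"construct {self.name!r} has no poles")
        n = len(self.poles)
        for i, j in self.dipoles:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValidationError(
                    f"construct {self.name!r}: invalid dipole ({i}, {j})")

    @classmethod
    def from_dict(cls, data: dict) -> "Construct":
        poles = tuple(
            (p["label"], tuple((w["lemma"], w["pos"]) for w in p["words"]))
            for p in data["poles"])
        dipoles = tuple((int(i), int(j)) for i, j in data.get("dipoles", []))
        return cls(name=data["name"], poles=poles, dipoles=dipoles)

    @classmethod
    def from_json(cls, path: str | Path) -> "Construct":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "poles": [{"label": label,
                       "words": [{"lemma": l, "pos": p} for l, p in words]}
                      for label, words in self.poles],
            "dipoles": [list(d) for d in self.dipoles],
        }


@dataclass
class MappedPole:
    """One pole resolved against a lexicon."""

    label: str
    words: list[tuple[Key, tuple[float, float], AtlasCell]]
    missing: list[Key]

    @property
    def positions(self) -> np.ndarray:
        return np.array([pos for _, pos, _ in self.words], dtype=float)

    @property
    def centroid(self) -> tuple[float, float]:
        p = self.positions.mean(axis=0)
        return (float(p[0]), float(p[1]))

    @property
    def modal_cell(self) -> AtlasCell:
        """The cell holding most of the pole's words.

        Ties break toward the cell nearest the pole centroid, then
        lexicographically on (affiliation, dominance).
        """
        counts: dict[AtlasCell, int] = {}
        for _, _, cell in self.words:
            counts[cell] = counts.get(cell, 0) + 1
        best = max(counts.values())
        tied = [c for c, n in counts.items() if n == best]
        cx, cy = self.centroid
        tied.sort(key=lambda c: (math.hypot(c.affiliation - cx, c.dominance - cy),
                                 c.affiliation, c.dominance))
        return tied[0]

    @property
    def single_cell(self) -> bool:
        cells = {cell for _, _, cell in self.words}
        return len(cells) == 1

    def representative_point(self) -> tuple[float, float]:
        """Cell coordinates when the pole occupies a single cell, else the
        centroid of its word positions."""
        if self.single_cell:
            c = self.words[0][2]
            return (float(c.affiliation), float(c.dominance))
        return self.centroid


@dataclass
class MappedConstruct:
    """A construct resolved against a scored lexicon."""

    name: str
    poles: list[MappedPole]
    dipoles: tuple[tuple[int, int], ...] = ()

    @property
    def coverage(self) -> float:
        found = sum(len(p.words) for p in self.poles)
        listed = found + sum(len(p.missing) for p in self.poles)
        return found / listed if listed else 0.0


def map_construct(construct: Construct, lexicon: Lexicon) -> MappedConstruct:
    """Resolve every construct word to its lexicon position and cell.

    Words absent from the lexicon (or present but unscored) are skipped
    with a logged warning and lower the coverage.  A pole with no
    resolvable word at all is an error.
    """
    poles: list[MappedPole] = []
    for label, word_keys in construct.poles:
        words, missing = [], []
        for key in word_keys:
            entry = lexicon.get(key)
            if entry is None or not entry.scored:
                logger.warning("construct %s, pole %s: %r not available in lexicon",
                               construct.name, label, key)
                missing.append(key)
                continue
            words.append((key, entry.position, entry.cell))
        if not words:
            raise EmptyPoleError(
                f"construct {construct.name!r}: pole {label!r} has no words "
                "resolvable in the lexicon")
        poles.append(MappedPole(label=label, words=words, missing=missing))
    return MappedConstruct(name=construct.name, poles=poles,
                           dipoles=construct.dipoles)


# ---------------------------------------------------------------------------
# Kernel density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """A Gaussian kernel density over the atlas square, unit mass."""

    x: np.ndarray            # affiliation axis nodes
    y: np.ndarray            # dominance axis nodes
    values: np.ndarray       # shape (len(x), len(y)), affiliation-major
    bandwidth: tuple[float, float]

    @property
    def resolution(self) -> int:
        return len(self.x)

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.values, self.y, axis=1), self.x))


def scott_bandwidth(points: np.ndarray, floor: float = 0.3) -> tuple[float, float]:
    """Scott's rule for a bivariate sample, n^(-1/6) * std per axis,
    floored so single points and degenerate spreads stay usable."""
    n = len(points)
    std = points.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    factor = n ** (-1.0 / 6.0)
    return (float(max(std[0] * factor, floor)),
            float(max(std[1] * factor, floor)))


def density_grid(points, bandwidth: float | tuple[float, float] | None = None,
                 resolution: int = 101) -> DensityGrid:
    """Evaluate a Gaussian kernel density on a regular grid over [-2, 2]^2.

    Mass falling outside the square is clipped: the grid is renormalized
    to unit integral over the square.  Deterministic for fixed inputs.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValidationError("density_grid requires at least one point")
    if bandwidth is None:
        bw = scott_bandwidth(pts)
    elif np.isscalar(bandwidth):
        bw = (float(bandwidth), float(bandwidth))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1]))
    if bw[0] <= 0 or bw[1] <= 0:
        raise ValidationError(f"bandwidth must be positive, got {bw}")
    x = np.linspace(-2.0, 2.0, resolution)
    y = np.linspace(-2.0, 2.0, resolution)
    # kernel sum, vectorized over (grid x, grid y, points)
    dx = (x[:, None] - pts[None, :, 0]) / bw[0]
    dy = (y[:, None] - pts[None, :, 1]) / bw[1]
    gx = np.exp(-0.5 * dx**2)          # (R, N)
    gy = np.exp(-0.5 * dy**2)          # (R, N)
    values = gx @ gy.T                  # (R, R), sum over points
    values /= 2 * np.pi * bw[0] * bw[1] * len(pts)
    grid = DensityGrid(x=x, y=y, values=values, bandwidth=bw)
    mass = grid.integral()
    if mass <= 0:
        raise ValidationError("density grid has no mass on the atlas square")
    grid.values = values / mass
    return grid


# ---------------------------------------------------------------------------
# Efficacy measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficacyMeasures:
    """One efficacy-table row: completeness, diffusion, discrimination."""

    completeness: float              # exact fraction in [0, 1]
    diffusion: float                 # exact fraction in [0, 1]
    discrimination: float | None     # mean dipole distance, None if no dipoles
    dipole_count: int

    @property
    def completeness_percent(self) -> int:
        return round(self.completeness * 100)

    @property
    def diffusion_percent(self) -> int:
        return round(self.diffusion * 100)

    def display(self) -> dict[str, str]:
        return {
            "diffusion": f"{self.diffusion_percent}%",
            "discrimination": ("N/A" if self.discrimination is None
                               else f"{self.discrimination:.1f}"),
            "completeness": f"{self.completeness_percent}%",
            "dipoles": str(self.dipole_count),
        }


def completeness(mapped: MappedConstruct) -> float:
    """Fraction of the 24 non-centre cells covered by a pole's modal cell."""
    cells = {p.modal_cell for p in mapped.poles}
    cells.discard(CENTRE_CELL)
    return len(cells) / N_DESIGN_CELLS


def diffusion(mapped: MappedConstruct) -> float:
    """Pooled fraction of mapped words outside their pole's modal cell."""
    total = sum(len(p.words) for p in mapped.poles)
    if total == 0:
        raise ValidationError("diffusion undefined: no mapped words")
    outside = sum(
        sum(1 for _, _, cell in p.words if cell != p.modal_cell)
        for p in mapped.poles)
    return outside / total


def discrimination(mapped: MappedConstruct) -> float | None:
    """Mean distance between the representative points of each dipole's
    poles; ``None`` (displayed N/A) when the construct has no dipoles."""
    if not mapped.dipoles:
        return None
    dists = []
    for i, j in mapped.dipoles:
        (xa, ya) = mapped.poles[i].representative_point()
        (xb, yb) = mapped.poles[j].representative_point()
        dists.append(math.hypot(xa - xb, ya - yb))
    return float(np.mean(dists))


def measures(mapped: MappedConstruct) -> EfficacyMeasures:
    """All three efficacy measures plus the dipole count."""
    return EfficacyMeasures(
        completeness=completeness(mapped),
        diffusion=diffusion(mapped),
        discrimination=discrimination(mapped),
        dipole_count=len(mapped.dipoles),
    )


def pole_vector(mapped: MappedConstruct, positive: int = 0,
                negative: int = 1) -> tuple[float, float]:
    """The construct's direction: positive-pole centroid minus
    negative-pole centroid."""
    px, py = mapped.poles[positive].centroid
    nx_, ny = mapped.poles[negative].centroid
    return (px - nx_, py - ny)


def cosine_correlation(vector_a, vector_b) -> float:
    """Cosine of the angle between two construct vectors, in [-1, 1]."""
    va = np.asarray(vector_a, dtype=float)
    vb = np.asarray(vector_b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValidationError("cosine correlation undefined for a zero vector")
    return float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
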