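"""The atlas grid: a 5x5 ordinal division of the affiliation and dominance axes.

Affiliation runs horizontally (-2 enduring disaffiliation ... +2 enduring
affiliation) and dominance vertically (-2 enduring submission ... +2 enduring
dominance).  The 25 integer cells tile the continuous square [-2, 2]^2 in
which words live; the centre cell (0, 0) holds neutral or involuntary
behaviours and plays no part in questionnaire design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

GRID_MIN = -2
GRID_MAX = 2

#: Inputs may overshoot the square by at most this much before snapping.
CLAMP_TOLERANCE = 1e-9


@dataclass(frozen=True, order=True)
class AtlasCell:
    """One of the 25 integer (affiliation, dominance) grid cells."""

    affiliation: int
    dominance: int

    def __post_init__(self) -> None:
        for name, v in (("affiliation", self.affiliation), ("dominance", self.dominance)):
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValidationError(f"cell {name} must be an integer, got {v!r}")
            if not GRID_MIN <= v <= GRID_MAX:
                raise ValidationError(f"cell {name}={v} outside [{GRID_MIN}, {GRID_MAX}]")

    def reflected(self) -> "AtlasCell":
        """The cell on the opposite side of the atlas, through the origin."""
        return AtlasCell(-self.affiliation, -self.dominance)

    def distance(self, other: "AtlasCell") -> float:
        return math.hypot(self.affiliation - other.affiliation,
                          self.dominance - other.dominance)

    @property
    def is_centre(self) -> bool:
        return self.affiliation == 0 and self.dominance == 0

    def as_tuple(self) -> tuple[int, int]:
        return (self.affiliation, self.dominance)

    def __str__(self) -> str:
        return f"({self.affiliation},{self.dominance})"


CENTRE_CELL = AtlasCell(0, 0)

#: All 25 cells, lexicographic in (affiliation, dominance).
ALL_CELLS: tuple[AtlasCell, ...] = tuple(
    AtlasCell(a, d)
    for a in range(GRID_MIN, GRID_MAX + 1)
    for d in range(GRID_MIN, GRID_MAX + 1)
)

#: The 24 cells eligible for questionnaire design (centre excluded).
NON_CENTRE_CELLS: tuple[AtlasCell, ...] = tuple(
    c for c in ALL_CELLS if not c.is_centre
)


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero keeps the map symmetric under negation,
    # which the diametric-opposition rule requires
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def snap_to_cell(affiliation: float, dominance: float) -> AtlasCell:
    """Snap a continuous position in [-2, 2]^2 to its nearest atlas cell.

    Each coordinate is rounded half-away-from-zero (so +/-0.5 leaves the
    neutral band), then clamped to the grid.  Idempotent on integer input.

    Raises
    ------
    ValidationError
        If a coordinate is non-finite or beyond the square by more than
        the clamping tolerance.
    """
    out = []
    for name, v in (("affiliation", affiliation), ("dominance", dominance)):
        v = float(v)
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v!r}")
        if v < GRID_MIN - CLAMP_TOLERANCE or v > GRID_MAX + CLAMP_TOLERANCE:
            raise ValidationError(f"{name}={v} outside the atlas square [-2, 2]")
        v = min(max(v, GRID_MIN), GRID_MAX)
        out.append(min(max(_round_half_away(v), GRID_MIN), GRID_MAX))
    return AtlasCell(out[0], out[1])


def reflection_pairs() -> tuple[tuple[AtlasCell, AtlasCell], ...]:
    """The 12 unordered pairs joining each non-centre cell to its reflection.

    Each pair is oriented with the lexicographically smaller cell first,
    matching the left/right orientation of printed dipole questionnaires.
    """
    pairs = []
    for c in NON_CENTRE_CELLS:
        r = c.reflected()
        if c < r:
            pairs.append((c, r))
    return tuple(pairs)
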