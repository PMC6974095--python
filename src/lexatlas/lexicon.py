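"""Word catalogue: entries keyed by (lemma, part of speech), TSV I/O,
cell occupancy tabulation, and the diametric-opposition pair validator.

The identity key is (lemma, pos), not the lemma alone: the same surface
form may carry different positions under different parts of speech
('humble' as an adjective sits at (1,-2); as a verb at (-2,1)).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ConflictError, FormatError, KeyLookupError, ValidationError
from .grid import ALL_CELLS, GRID_MAX, GRID_MIN, AtlasCell, snap_to_cell

POS_VALUES = ("adjective", "noun", "verb", "idiom")
DOMAIN_VALUES = ("behaviour", "emotion", "personality", "power")
PROVENANCE_VALUES = ("judged", "propagated", "synthetic", "unset")

Key = tuple[str, str]  # (lemma, pos)

LEXICON_COLUMNS = ("lemma", "pos", "domain", "affiliation",
                   "dominance", "anchor", "provenance")


@dataclass(frozen=True)
class WordEntry:
    """One catalogued word sense with its (optional) atlas position.

    ``affiliation``/``dominance`` are continuous scores in [-2, 2] or
    ``None`` when the word has not been placed yet.  Anchors are words
    whose position was fixed by expert judging; they never move during
    propagation and must be scored.
    """

    lemma: str
    pos: str
    domain: str
    affiliation: float | None = None
    dominance: float | None = None
    anchor: bool = False
    provenance: str = "unset"

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValidationError("lemma must be non-empty")
        if self.pos not in POS_VALUES:
            raise ValidationError(f"pos {self.pos!r} not in {POS_VALUES}")
        if self.domain not in DOMAIN_VALUES:
            raise ValidationError(f"domain {self.domain!r} not in {DOMAIN_VALUES}")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValidationError(
                f"provenance {self.provenance!r} not in {PROVENANCE_VALUES}")
        if (self.affiliation is None) != (self.dominance is None):
            raise ValidationError(
                f"{self.lemma}/{self.pos}: affiliation and dominance must be "
                "both set or both unset")
        for name, v in (("affiliation", self.affiliation),
                        ("dominance", self.dominance)):
            if v is None:
                continue
            if not math.isfinite(v):
                raise ValidationError(f"{self.lemma}/{self.pos}: {name} not finite")
            if not GRID_MIN <= v <= GRID_MAX:
                raise ValidationError(
                    f"{self.lemma}/{self.pos}: {name}={v} outside [-2, 2]")
        if self.anchor and self.affiliation is None:
            raise ValidationError(
                f"{self.lemma}/{self.pos}: anchor entries must be scored")

    @property
    def key(self) -> Key:
        return (self.lemma, self.pos)

    @property
    def scored(self) -> bool:
        return self.affiliation is not None

    @property
    def position(self) -> tuple[float, float]:
        if not self.scored:
            raise ValidationError(f"{self.lemma}/{self.pos} has no position")
        return (float(self.affiliation), float(self.dominance))

    @property
    def cell(self) -> AtlasCell:
        return snap_to_cell(*self.position)


class Lexicon:
    """An insertion-ordered collection of :class:`WordEntry`, unique by key."""

    def __init__(self, entries: Iterable[WordEntry] = ()) -> None:
        self._entries: dict[Key, WordEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: WordEntry) -> None:
        if entry.key in self._entries:
            raise ValidationError(
                f"duplicate key ({entry.lemma!r}, {entry.pos!r})")
        self._entries[entry.key] = entry

    def replace_entry(self, entry: WordEntry) -> None:
        if entry.key not in self._entries:
            raise KeyLookupError(f"unknown key {entry.key}")
        self._entries[entry.key] = entry

    def __getitem__(self, key: Key) -> WordEntry:
        try:
            return self._entries[key]
        except KeyError:
            raise KeyLookupError(f"word {key[0]!r} ({key[1]}) not in lexicon") from None

    def get(self, key: Key) -> WordEntry | None:
        return self._entries.get(key)

    def __contains__(self, key: Key) -> bool:
        return key in self._entries

    def __iter__(self) -> Iterator[WordEntry]:
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def keys(self) -> list[Key]:
        return list(self._entries)

    def sorted_keys(self) -> list[Key]:
        # plain codepoint order: reproducible, locale-free "alphabetical"
        return sorted(self._entries)

    def scored_entries(self) -> list[WordEntry]:
        return [e for e in self if e.scored]

    def unscored_keys(self) -> list[Key]:
        return [e.key for e in self if not e.scored]

    def anchors(self) -> list[WordEntry]:
        return [e for e in self if e.anchor]

    def copy(self) -> "Lexicon":
        lx = Lexicon()
        lx._entries = dict(self._entries)
        return lx


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _format_score(v: float | None) -> str:
    if v is None:
        return ""
    v = float(v)
    if v == int(v):
        return str(int(v))
    return repr(v)


def _parse_score(text: str, row: int, column: str) -> float | None:
    if text == "":
        return None
    try:
        v = float(text)
    except ValueError:
        raise ValidationError(f"row {row}: {column} {text!r} is not a number") from None
    if not math.isfinite(v) or not GRID_MIN <= v <= GRID_MAX:
        raise ValidationError(f"row {row}: {column}={text} outside [-2, 2]")
    return v


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a lexicon from tab-separated UTF-8 text.

    The header must name the columns lemma/pos/domain/affiliation/dominance/
    anchor/provenance.  Unset scores are empty fields.  Duplicate
    (lemma, pos) keys are rejected.
    """
    path = Path(path)
    lx = Lexicon()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        for col in LEXICON_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):
            try:
                entry = WordEntry(
                    lemma=row["lemma"],
                    pos=row["pos"],
                    domain=row["domain"],
                    affiliation=_parse_score(row["affiliation"], i, "affiliation"),
                    dominance=_parse_score(row["dominance"], i, "dominance"),
                    anchor=_parse_bool(row["anchor"], i),
                    provenance=row["provenance"] or "unset",
                )
                lx.add(entry)
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from None
    return lx


def _parse_bool(text: str, row: int) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"row {row}: anchor {text!r} is not a boolean")


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Write a lexicon in the canonical TSV dialect (stable byte-for-byte)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(LEXICON_COLUMNS) + "\n")
        for e in lexicon:
            fh.write("\t".join([
                e.lemma, e.pos, e.domain,
                _format_score(e.affiliation), _format_score(e.dominance),
                "true" if e.anchor else "false",
                e.provenance,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Occupancy tabulation
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Word counts per (domain, cell), with marginals, like a frequency
    table of the atlas."""

    counts: dict[str, np.ndarray]          # domain -> 5x5 (affiliation x dominance)
    excluded: list[Key] = field(default_factory=list)

    def count(self, domain: str, cell: AtlasCell) -> int:
        return int(self.counts[domain][cell.affiliation + 2, cell.dominance + 2])

    def domain_total(self, domain: str) -> int:
        return int(self.counts[domain].sum())

    def cell_total(self, cell: AtlasCell) -> int:
        return int(sum(m[cell.affiliation + 2, cell.dominance + 2]
                       for m in self.counts.values()))

    def affiliation_totals(self) -> dict[int, int]:
        return {a: int(sum(m[a + 2, :].sum() for m in self.counts.values()))
                for a in range(GRID_MIN, GRID_MAX + 1)}

    def dominance_totals(self) -> dict[int, int]:
        return {d: int(sum(m[:, d + 2].sum() for m in self.counts.values()))
                for d in range(GRID_MIN, GRID_MAX + 1)}

    @property
    def grand_total(self) -> int:
        return int(sum(m.sum() for m in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame with one row per (domain, cell)."""
        rows = [
            {"domain": dom, "affiliation": c.affiliation,
             "dominance": c.dominance, "count": self.count(dom, c)}
            for dom in self.counts for c in ALL_CELLS
        ]
        return pd.DataFrame(rows)


def occupancy_table(lexicon: Lexicon,
                    domains: Iterable[str] = DOMAIN_VALUES) -> CellTable:
    """Tabulate scored words per (domain, cell); unscored words are
    excluded from the counts and listed in the table's exclusion report."""
    counts = {dom: np.zeros((5, 5), dtype=int) for dom in domains}
    excluded: list[Key] = []
    for e in lexicon:
        if not e.scored:
            excluded.append(e.key)
            continue
        if e.domain not in counts:
            continue
        c = e.cell
        counts[e.domain][c.affiliation + 2, c.dominance + 2] += 1
    return CellTable(counts=counts, excluded=excluded)


# ---------------------------------------------------------------------------
# Antonym-pair validation and symmetrization
# ---------------------------------------------------------------------------

@dataclass
class PairReport:
    """Outcome of the diametric-opposition check on a list of word pairs."""

    conforming: list[tuple[Key, Key]]
    nonconforming: list[tuple[Key, Key]]

    @property
    def n_conforming(self) -> int:
        return len(self.conforming)

    @property
    def n_nonconforming(self) -> int:
        return len(self.nonconforming)


def validate_antonym_pairs(lexicon: Lexicon,
                           pairs: Iterable[tuple[Key, Key]]) -> PairReport:
    """Check, for each antonym pair, that the two cells are reflections of
    each other through the origin (the archetypal-pair criterion).

    Self-pairs are rejected with a validation error; absent words raise a
    lookup error naming the lemma.
    """
    conforming: list[tuple[Key, Key]] = []
    nonconforming: list[tuple[Key, Key]] = []
    for key_a, key_b in pairs:
        if key_a == key_b:
            raise ValidationError(f"self-pair {key_a} is not a valid antonym pair")
        a, b = lexicon[key_a], lexicon[key_b]
        for e in (a, b):
            if not e.scored:
                raise ValidationError(f"{e.lemma}/{e.pos} is unscored")
        if a.cell.reflected() == b.cell:
            conforming.append((key_a, key_b))
        else:
            nonconforming.append((key_a, key_b))
    return PairReport(conforming=conforming, nonconforming=nonconforming)


def symmetrize_pair(entry_a: WordEntry,
                    entry_b: WordEntry) -> tuple[WordEntry, WordEntry]:
    """Force an antonym pair into exact opposition through the origin.

    The anchored member (or ``entry_a`` on a tie) keeps its position and the
    other is moved to its reflection.  Two anchors with non-opposite scores
    conflict: anchors are never silently overwritten.
    """
    if not entry_a.scored and not entry_b.scored:
        raise ValidationError(
            f"cannot symmetrize {entry_a.lemma}/{entry_b.lemma}: neither is scored")
    if entry_a.anchor and entry_b.anchor:
        ra = (-entry_a.affiliation, -entry_a.dominance)
        if (math.isclose(ra[0], entry_b.affiliation, abs_tol=1e-12)
                and math.isclose(ra[1], entry_b.dominance, abs_tol=1e-12)):
            return entry_a, entry_b
        raise ConflictError(
            f"anchors {entry_a.lemma}/{entry_a.pos} and "
            f"{entry_b.lemma}/{entry_b.pos} are not exact opposites")
    if entry_b.anchor or (not entry_a.scored and entry_b.scored):
        keeper, mover = entry_b, entry_a
    else:
        keeper, mover = entry_a, entry_b
    moved = replace(mover,
                    affiliation=-keeper.affiliation,
                    dominance=-keeper.dominance)
    if keeper is entry_a:
        return keeper, moved
    return moved, keeper
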