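"""Typed synonym/antonym graph over (lemma, pos) keys.

Edges are undirected, stored canonically ordered, carry a relation
(synonym or antonym) and a source count: how many reference thesauri
listed the relation (1 or 2).  Backed by a :class:`networkx.Graph`.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import FormatError, ValidationError
from .lexicon import Key

RELATIONS = ("synonym", "antonym")

EDGE_COLUMNS = ("lemma_a", "pos_a", "lemma_b", "pos_b", "relation", "sources")


class ThesaurusGraph:
    """Undirected typed word-relation graph."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    def add_node(self, key: Key) -> None:
        self._g.add_node(key)

    def add_edge(self, key_a: Key, key_b: Key, relation: str,
                 sources: int = 1) -> None:
        if key_a == key_b:
            raise ValidationError(f"self-edge on {key_a} not allowed")
        if relation not in RELATIONS:
            raise ValidationError(f"relation {relation!r} not in {RELATIONS}")
        if sources not in (1, 2):
            raise ValidationError(f"sources must be 1 or 2, got {sources!r}")
        a, b = sorted((key_a, key_b))
        self._g.add_edge(a, b, relation=relation, sources=sources)

    @property
    def nodes(self) -> set[Key]:
        return set(self._g.nodes)

    def __contains__(self, key: Key) -> bool:
        return key in self._g

    def neighbors(self, key: Key) -> list[tuple[Key, str, int]]:
        """All neighbours of ``key`` with relation type and source count."""
        if key not in self._g:
            return []
        return [(nbr, data["relation"], data["sources"])
                for nbr, data in self._g.adj[key].items()]

    def degree(self, key: Key) -> int:
        return self._g.degree(key) if key in self._g else 0

    def edges(self) -> Iterator[tuple[Key, Key, str, int]]:
        """Edges in canonical order (endpoints sorted, edges sorted)."""
        items = [(a, b, d["relation"], d["sources"])
                 for a, b, d in self._g.edges(data=True)]
        return iter(sorted(items))

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edge_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in RELATIONS}
        for _, _, d in self._g.edges(data=True):
            counts[d["relation"]] += 1
        return counts

    def connected_components(self) -> list[set[Key]]:
        return [set(c) for c in nx.connected_components(self._g)]

    def subgraph_nodes(self, keys: Iterable[Key]) -> "ThesaurusGraph":
        sub = ThesaurusGraph()
        sub._g = self._g.subgraph(keys).copy()
        return sub


def read_edges(path: str | Path) -> ThesaurusGraph:
    """Read an edge list from tab-separated UTF-8 text."""
    path = Path(path)
    g = ThesaurusGraph()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        for col in EDGE_COLUMNS:
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing required column {col!r}")
        for i, row in enumerate(reader, start=2):
            try:
                g.add_edge((row["lemma_a"], row["pos_a"]),
                           (row["lemma_b"], row["pos_b"]),
                           relation=row["relation"],
                           sources=int(row["sources"]))
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}: row {i}: {exc}") from None
    return g


def write_edges(graph: ThesaurusGraph, path: str | Path) -> None:
    """Write the edge list in canonical TSV form (stable byte-for-byte)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for (la, pa), (lb, pb), rel, src in graph.edges():
            fh.write(f"{la}\t{pa}\t{lb}\t{pb}\t{rel}\t{src}\n")
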