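"""Path collections on networks.

A *path* is a finite ordered sequence of node labels traversed on a
(directed) network; collections of paths are multisets in which each
distinct node sequence carries an integer observation count.  This module
provides parsing and serialisation of plain-text path files, validation,
instance-level train/validation splitting, derivation of the observed
first-order topology, and enumeration of prefix-target pairs for
next-element evaluation.

File dialect: one path per line, labels separated by a configurable
delimiter (default comma); an optional observation count follows a
semicolon; ``#`` starts a comment.
"""
from __future__ import annotations

import io
import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from os import PathLike
from typing import TextIO, Union

import numpy as np

#: Reserved symbol marking the virtual start of every path.
START_SYMBOL = "*"
#: Reserved symbol marking path termination; may appear as a prediction
#: target but never as a node label.
END_SYMBOL = "†"  # †

RESERVED_SYMBOLS = frozenset({START_SYMBOL, END_SYMBOL})

COUNT_SEPARATOR = ";"
COMMENT_CHAR = "#"


class PathFileError(ValueError):
    """Raised when a path file line cannot be parsed."""


class EmptyCollectionError(ValueError):
    """Raised when an operation requires a non-empty path collection."""


def _validate_nodes(nodes: tuple[str, ...]) -> None:
    if len(nodes) < 1:
        raise ValueError("a path must contain at least one node")
    for label in nodes:
        if not isinstance(label, str) or not label:
            raise ValueError(f"node labels must be non-empty strings, got {label!r}")
        if label in RESERVED_SYMBOLS:
            raise ValueError(f"label {label!r} is reserved for the start/terminal state")


@dataclass(frozen=True)
class Path:
    """An observed node sequence with its observation count."""

    nodes: tuple[str, ...]
    count: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        _validate_nodes(self.nodes)
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise ValueError(f"count must be a positive integer, got {self.count!r}")

    @property
    def length(self) -> int:
        return len(self.nodes)


class PathCollection:
    """Multiset of variable-length paths with integer frequencies.

    Internally a mapping from node-label tuples to counts.  ``m`` denotes
    the total number of path instances (sum of counts) and ``l_max`` the
    longest path's node count.
    """

    def __init__(self, paths: Iterable[Path] = ()) -> None:
        self._counts: dict[tuple[str, ...], int] = {}
        for p in paths:
            self.add(p.nodes, p.count)

    def add(self, nodes: Iterable[str], count: int = 1) -> None:
        nodes = tuple(nodes)
        _validate_nodes(nodes)
        if count < 1:
            raise ValueError("count must be positive")
        self._counts[nodes] = self._counts.get(nodes, 0) + int(count)

    # -- views ---------------------------------------------------------
    @property
    def paths(self) -> list[Path]:
        """Distinct paths in canonical (sorted) order."""
        return [Path(n, c) for n, c in sorted(self._counts.items())]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return dict(self._counts)

    @property
    def node_set(self) -> set[str]:
        return {v for nodes in self._counts for v in nodes}

    @property
    def total_paths(self) -> int:
        """m — number of path instances, counting multiplicity."""
        return sum(self._counts.values())

    @property
    def num_unique(self) -> int:
        return len(self._counts)

    @property
    def max_length(self) -> int:
        if not self._counts:
            return 0
        return max(len(n) for n in self._counts)

    def get_count(self, nodes: Iterable[str]) -> int:
        return self._counts.get(tuple(nodes), 0)

    def __contains__(self, nodes: object) -> bool:
        return tuple(nodes) in self._counts  # type: ignore[arg-type]

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[Path]:
        return iter(self.paths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathCollection):
            return NotImplemented
        return self._counts == other._counts

    def __repr__(self) -> str:
        return (
            f"PathCollection(unique={self.num_unique}, m={self.total_paths}, "
            f"|V|={len(self.node_set)}, l_max={self.max_length})"
        )

    def transitions(self) -> Iterator[tuple[tuple[str, str], int]]:
        """Yield each distinct consecutive node pair with its total count."""
        tally: dict[tuple[str, str], int] = {}
        for nodes, c in self._counts.items():
            for v, w in zip(nodes[:-1], nodes[1:]):
                tally[(v, w)] = tally.get((v, w), 0) + c
        yield from sorted(tally.items())


@dataclass(frozen=True)
class ObservedTopology:
    """Binary first-order adjacency over an ordered node list.

    ``adjacency[i, j] == 1`` iff the transition ``nodes[i] -> nodes[j]``
    is possible (for a topology derived from data: observed at least once).
    """

    nodes: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        object.__setattr__(self, "adjacency", adj.astype(np.int64))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def index(self, label: str) -> int:
        return self.nodes.index(label)

    def has_edge(self, v: str, w: str) -> bool:
        try:
            return bool(self.adjacency[self.index(v), self.index(w)])
        except ValueError:
            return False

    def successors(self, v: str) -> list[str]:
        i = self.nodes.index(v)
        return [self.nodes[j] for j in np.flatnonzero(self.adjacency[i])]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] | None = None
    ) -> "ObservedTopology":
        edges = list(edges)
        if nodes is None:
            labels = sorted({v for e in edges for v in e})
        else:
            labels = list(nodes)
        idx = {v: i for i, v in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for v, w in edges:
            adj[idx[v], idx[w]] = 1
        return cls(tuple(labels), adj)


def observed_adjacency(collection: PathCollection) -> ObservedTopology:
    """Derive the binary topology whose edges are the observed transitions.

    An entry is 1 iff the node pair occurs consecutively on at least one
    path of the collection, regardless of frequency.
    """
    if collection.total_paths == 0:
        raise EmptyCollectionError("cannot derive a topology from an empty collection")
    nodes = tuple(sorted(collection.node_set))
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=np.int64)
    for (v, w), _ in collection.transitions():
        adj[idx[v], idx[w]] = 1
    return ObservedTopology(nodes, adj)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

Source = Union[str, PathLike, TextIO]


def _open_text(source: Source, mode: str):
    if isinstance(source, (str, PathLike)):
        return open(source, mode, encoding="utf-8"), True
    return source, False


def read_path_file(
    source: Source,
    delimiter: str = ",",
    count_column: bool = True,
) -> PathCollection:
    """Parse a plain-text path file into a :class:`PathCollection`.

    Each non-empty, non-comment line holds delimited node labels, optionally
    followed by ``;<count>``.  Identical node sequences accumulate counts.
    Raises :class:`PathFileError` on malformed lines and
    :class:`EmptyCollectionError` if no paths are found.
    """
    stream, close = _open_text(source, "r")
    collection = PathCollection()
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith(COMMENT_CHAR):
                continue
            count = 1
            if count_column and COUNT_SEPARATOR in line:
                body, _, count_field = line.rpartition(COUNT_SEPARATOR)
                try:
                    count = int(count_field.strip())
                except ValueError as exc:
                    raise PathFileError(
                        f"line {lineno}: malformed count field {count_field!r}"
                    ) from exc
                if count < 1:
                    raise PathFileError(f"line {lineno}: count must be positive")
                line = body
            labels = tuple(s.strip() for s in line.split(delimiter))
            try:
                collection.add(labels, count)
            except ValueError as exc:
                raise PathFileError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            stream.close()
    if collection.total_paths == 0:
        raise EmptyCollectionError("path file contains no paths")
    return collection


def write_path_file(
    collection: PathCollection,
    sink: Source,
    delimiter: str = ",",
) -> None:
    """Write a collection in the path-file dialect (counts included).

    Round-trips exactly with :func:`read_path_file`.
    """
    stream, close = _open_text(sink, "w")
    try:
        for p in collection.paths:
            stream.write(delimiter.join(p.nodes) + f"{COUNT_SEPARATOR}{p.count}\n")
    finally:
        if close:
            stream.close()


def read_edge_list(source: Source, delimiter: str | None = None) -> ObservedTopology:
    """Read a declared topology from an edge-list file (two labels per line)."""
    stream, close = _open_text(source, "r")
    edges = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith(COMMENT_CHAR):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            if len(parts) != 2:
                raise PathFileError(f"line {lineno}: expected two labels, got {parts!r}")
            edges.append((parts[0].strip(), parts[1].strip()))
    finally:
        if close:
            stream.close()
    if not edges:
        raise EmptyCollectionError("edge list contains no edges")
    return ObservedTopology.from_edges(edges)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_train_validation(
    collection: PathCollection,
    validation_fraction: float,
    seed: int,
) -> tuple[PathCollection, PathCollection]:
    """Split path *instances* uniformly at random into train/validation.

    The split unit is an individual observation (a path counted with its
    multiplicity), so a path observed 10 times may land partly on each
    side.  The two parts sum exactly to the original collection and the
    split is reproducible under a fixed seed.
    """
    if not (0.0 < validation_fraction < 1.0):
        raise ValueError("validation_fraction must lie strictly between 0 and 1")
    m = collection.total_paths
    if m < 2:
        raise ValueError("need at least two path instances to split")
    rng = np.random.default_rng(seed)
    items = sorted(collection.counts.items())
    counts = np.array([c for _, c in items], dtype=np.int64)
    n_val = int(round(m * validation_fraction))
    n_val = min(max(n_val, 0), m)
    val_counts = rng.multivariate_hypergeometric(counts, n_val)
    train, val = PathCollection(), PathCollection()
    for (nodes, c), cv in zip(items, val_counts):
        if cv:
            val.add(nodes, int(cv))
        if c - cv:
            train.add(nodes, int(c - cv))
    return train, val


# ---------------------------------------------------------------------------
# prefix-target enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrefixTarget:
    """One evaluation item: a prefix of visited nodes and the true next element."""

    prefix: tuple[str, ...]
    target: str  # node label or END_SYMBOL
    weight: float


@dataclass
class PrefixTargetSet:
    """Weighted prefix-target pairs for next-element evaluation.

    For each target occurrence the weights over its enumerated prefixes sum
    to the observation count of the source path, so each occurrence
    contributes one unit of evidence per observation regardless of how many
    prefix lengths were enumerated for it.
    """

    items: list[PrefixTarget] = field(default_factory=list)
    max_prefix: int = 6

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[PrefixTarget]:
        return iter(self.items)

    @property
    def total_weight(self) -> float:
        return math.fsum(it.weight for it in self.items)


def extract_prefix_targets(
    collection: PathCollection,
    max_prefix: int = 6,
    include_empty_prefix: bool = False,
) -> PrefixTargetSet:
    """Enumerate all prefix-target combinations up to ``max_prefix``.

    For every target position t >= 2 on every path, and for the terminal
    marker after the last node, prefixes of lengths n = 1..min(t-1,
    max_prefix) are emitted (truncated at the path start).  With
    ``include_empty_prefix`` the empty prefix (n = 0) is also emitted,
    which additionally makes the first node of each path a target.  Each
    prefix of a given target occurrence receives weight
    ``count / (number of prefixes for that occurrence)``.
    """
    if max_prefix < 1:
        raise ValueError("max_prefix must be >= 1")
    items: list[PrefixTarget] = []
    n_min = 0 if include_empty_prefix else 1
    for p in collection.paths:
        nodes = p.nodes
        l = len(nodes)
        # interior targets at 0-based index t (t preceding nodes available),
        # then the terminal marker with l preceding nodes.
        first = 0 if include_empty_prefix else 1
        targets = [(t, nodes[t]) for t in range(first, l)]
        targets.append((l, END_SYMBOL))
        for avail, target in targets:
            lengths = [n for n in range(n_min, min(avail, max_prefix) + 1)]
            if not lengths:
                continue
            w = p.count / len(lengths)
            for n in lengths:
                items.append(PrefixTarget(nodes[avail - n : avail], target, w))
    return PrefixTargetSet(items, max_prefix=max_prefix)
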