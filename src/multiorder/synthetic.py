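"""Synthetic path data with known ground truth.

Two generators: the six-node toy system with five colour-coded paths whose
frequencies control the true memory order, and planted multi-order models
(explicit stochastic rows over the extended state space) from which path
collections of any size can be sampled.  Both make every other module
testable with known answers and no external data.

The toy system has nodes A-F with edges A→C, B→C, C→D, D→E, D→F and the
five paths A→C, A→C→D→E, A→C→D→F, B→C→D→E, B→C→D→F.  With all five
frequencies equal, where a path ends is independent of where it started
and a maximum order of 2 suffices; concentrating frequency on A→C→D→E and
B→C→D→F plants a start-terminal dependency that only order 3 can express.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .generation import sample_collection
from .model import (
    END_STATE,
    START_STATE,
    MultiOrderModel,
    StateKey,
    fit_model,
)
from .paths import ObservedTopology, PathCollection

__all__ = [
    "TOY_PATHS",
    "ToySpec",
    "toy_collection",
    "toy_topology",
    "PlantedModelSpec",
    "planted_model",
    "planted_paths",
    "planted_from_collection",
    "random_planted_model",
]

#: The five toy paths, in frequency-vector order.
TOY_PATHS: tuple[tuple[str, ...], ...] = (
    ("A", "C"),
    ("A", "C", "D", "E"),
    ("A", "C", "D", "F"),
    ("B", "C", "D", "E"),
    ("B", "C", "D", "F"),
)


@dataclass(frozen=True)
class ToySpec:
    """Observation frequencies for the five toy paths."""

    frequencies: tuple[int, int, int, int, int] = (10, 10, 10, 10, 10)

    def __post_init__(self) -> None:
        if len(self.frequencies) != 5:
            raise ValueError("exactly five frequencies required")
        if any(f < 0 for f in self.frequencies):
            raise ValueError("frequencies must be non-negative")
        if not any(self.frequencies):
            raise ValueError("at least one frequency must be positive")


def toy_collection(spec: ToySpec | None = None) -> PathCollection:
    """The five-path toy multiset with the given frequencies."""
    spec = spec or ToySpec()
    out = PathCollection()
    for nodes, f in zip(TOY_PATHS, spec.frequencies):
        if f > 0:
            out.add(nodes, f)
    return out


def toy_topology() -> ObservedTopology:
    """The toy system's five-edge directed topology over nodes A-F."""
    return ObservedTopology.from_edges(
        [("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"), ("D", "F")],
        nodes="ABCDEF",
    )


# ---------------------------------------------------------------------------
# planted models
# ---------------------------------------------------------------------------


@dataclass
class PlantedModelSpec:
    """A known multi-order generative process to sample from.

    ``transition_rows`` maps each state to a stochastic row; every
    non-terminal state must reach the terminal state with positive
    probability so sampled walks terminate almost surely.
    """

    topology: ObservedTopology
    true_order: int
    transition_rows: dict[StateKey, dict[StateKey, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        for state, row in self.transition_rows.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"row of {state} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError("negative planted probability")


def planted_model(spec: PlantedModelSpec) -> MultiOrderModel:
    """Wrap planted rows as a model usable by sampling and prediction."""
    return MultiOrderModel(
        max_order=spec.true_order,
        probs={s: dict(r) for s, r in spec.transition_rows.items()},
        row_totals={s: 1 for s in spec.transition_rows},
        nodes=spec.topology.nodes,
        source_l_max=0,
    )


def planted_paths(spec: PlantedModelSpec, n: int, seed: int | None = None) -> PathCollection:
    """Sample n independent walks from * to † under the planted rows."""
    model = planted_model(spec)
    cap = 10 * max(spec.topology.n_nodes, spec.true_order)
    gen = sample_collection(model, n, spec.seed if seed is None else seed, max_length=cap)
    return gen.paths


def planted_from_collection(
    collection: PathCollection, true_order: int, seed: int = 0
) -> PlantedModelSpec:
    """Plant the multi-order model fitted to a collection at a given order.

    The fitted transition rows become the ground truth, e.g. the toy
    collection at order 2 (equal frequencies) or order 3 (start-terminal
    dependency instance) for order-recovery experiments.
    """
    from .paths import observed_adjacency

    model = fit_model(collection, true_order)
    return PlantedModelSpec(
        topology=observed_adjacency(collection),
        true_order=true_order,
        transition_rows={s: dict(r) for s, r in model.probs.items()},
        seed=seed,
    )


def _walk_tuples(topology: ObservedTopology, k: int) -> list[tuple[str, ...]]:
    tuples: list[tuple[str, ...]] = [(v,) for v in topology.nodes]
    for _ in range(k - 1):
        tuples = [t + (w,) for t in tuples for w in topology.successors(t[-1])]
    return tuples


def random_planted_model(
    n_nodes: int,
    out_degree: int,
    order: int,
    seed: int,
    end_prob: float = 0.2,
) -> PlantedModelSpec:
    """Plant a random model of a given true order on a random digraph.

    Builds a digraph where every node has ``out_degree`` random successors,
    then draws Dirichlet transition rows over the extended multi-order
    state space, reserving probability ``end_prob`` for termination at
    every tuple state (so the invariant that † is reachable from every
    state holds by construction).  Higher-order structure is genuine: each
    row of the deepest layer is drawn independently per memory tuple.
    """
    if not (0.0 < end_prob < 1.0):
        raise ValueError("end_prob must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = tuple(f"N{i}" for i in range(n_nodes))
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    for i in range(n_nodes):
        targets = rng.choice(
            [j for j in range(n_nodes) if j != i],
            size=min(out_degree, n_nodes - 1),
            replace=False,
        )
        adj[i, targets] = 1
    topology = ObservedTopology(labels, adj)

    rows: dict[StateKey, dict[StateKey, float]] = {}
    start_probs = rng.dirichlet(np.ones(n_nodes))
    rows[START_STATE] = {
        StateKey("tuple", (v,)): float(p) for v, p in zip(labels, start_probs)
    }
    for k in range(1, order + 1):
        for t in _walk_tuples(topology, k):
            succ = topology.successors(t[-1])
            if k < order:
                targets = [StateKey("tuple", t + (w,)) for w in succ]
            else:
                targets = [StateKey("tuple", t[1:] + (w,)) for w in succ]
            cont = rng.dirichlet(np.ones(len(targets))) * (1.0 - end_prob)
            row = {tgt: float(p) for tgt, p in zip(targets, cont)}
            row[END_STATE] = end_prob
            rows[StateKey("tuple", t)] = row
    return PlantedModelSpec(
        topology=topology, true_order=order, transition_rows=rows, seed=seed
    )
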