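"""Multi-order generative models of variable-length paths.

A multi-order model of maximum order K stacks higher-order Markov layers
of orders 1..K in a single block-structured transition matrix over an
extended state space: a virtual initial state ``*`` whose outgoing
transitions encode the distribution of path start nodes, tuple states
``(v_1, ..., v_k)`` encoding k-step memory for k <= K, and a virtual
terminal state ``†`` absorbing path ends from every layer.  A path of
length l maps onto a state sequence

    * -> (v_1) -> (v_1, v_2) -> ... -> (v_{l-K+1}, ..., v_l) -> †

of l + 2 states (l + 1 transitions): the memory prefix grows by one node
per step up to length K, then slides.  Transition counts are read off the
data; row-normalising the count matrix yields the generative model.

The single free parameter K is selected by AIC.  The degrees of freedom
account for structural zeros imposed by the first-order topology A:

    d(T^(K)) = |V| + sum_{k=1..K} sum_ij (A^k)_ij - 1

and the AIC argmin over K is equivalent to minimising the objective

    sum_{k<=K} sum_ij (A^k)_ij  -  sum_{t in S} ln P(t | T^(K)),

which this module computes alongside the full AIC.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import total_ordering
from os import PathLike
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .paths import (
    END_SYMBOL,
    START_SYMBOL,
    EmptyCollectionError,
    ObservedTopology,
    Path,
    PathCollection,
    observed_adjacency,
)

__all__ = [
    "StateKey",
    "START_STATE",
    "END_STATE",
    "node_state",
    "MultiOrderCounts",
    "MultiOrderModel",
    "ModelSelectionTable",
    "encode_state_sequence",
    "build_counts",
    "to_transition_model",
    "fit_model",
    "path_log_probability",
    "collection_log_likelihood",
    "adjacency_power_sums",
    "degrees_of_freedom",
    "possible_transitions",
    "aic_score",
    "selection_objective",
    "select_optimal_order",
    "model_to_json",
    "model_from_json",
    "export_matrix_market",
]


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------


@total_ordering
@dataclass(frozen=True)
class StateKey:
    """A state of the multi-order chain.

    ``kind`` is one of ``initial`` (the virtual start ``*``), ``terminal``
    (the absorbing end ``†``) or ``tuple`` (a k-th order memory state with
    k = len(labels)).  States order layer-major: ``*`` first, tuple states
    by layer then lexicographically, ``†`` last.
    """

    kind: str
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("initial", "terminal", "tuple"):
            raise ValueError(f"unknown state kind {self.kind!r}")
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.kind == "tuple" and len(self.labels) < 1:
            raise ValueError("tuple states need at least one label")
        if self.kind != "tuple" and self.labels:
            raise ValueError(f"{self.kind} state carries no labels")

    @property
    def order(self) -> int:
        """Layer index: 0 for ``*``, k for a k-tuple, +inf-like for ``†``."""
        return len(self.labels)

    def _sort_key(self) -> tuple:
        if self.kind == "initial":
            return (0, 0, ())
        if self.kind == "tuple":
            return (1, len(self.labels), self.labels)
        return (2, 0, ())

    def __lt__(self, other: "StateKey") -> bool:
        return self._sort_key() < other._sort_key()

    def __str__(self) -> str:
        if self.kind == "initial":
            return START_SYMBOL
        if self.kind == "terminal":
            return END_SYMBOL
        return "(" + ",".join(self.labels) + ")"


START_STATE = StateKey("initial")
END_STATE = StateKey("terminal")


def node_state(*labels: str) -> StateKey:
    """Convenience constructor for a tuple (memory) state."""
    return StateKey("tuple", tuple(labels))


def encode_state_sequence(path: Union[Path, Iterable[str]], K: int) -> list[StateKey]:
    """Map a path onto its multi-order state sequence.

    Returns ``*``, the growing prefixes up to length min(l, K), the sliding
    length-K windows, and ``†`` — i.e. l + 2 states joined by l + 1
    transitions for a path of length l.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    nodes = path.nodes if isinstance(path, Path) else tuple(path)
    l = len(nodes)
    states: list[StateKey] = [START_STATE]
    for j in range(1, min(l, K) + 1):
        states.append(StateKey("tuple", nodes[:j]))
    for i in range(K + 1, l + 1):
        states.append(StateKey("tuple", nodes[i - K : i]))
    states.append(END_STATE)
    return states


# ---------------------------------------------------------------------------
# counts and model
# ---------------------------------------------------------------------------


@dataclass
class MultiOrderCounts:
    """Block count matrix A^(K) in sparse row form.

    ``rows[s][s']`` counts observed transitions s -> s'.  Also records the
    node universe and longest path length of the source collection (used
    downstream for fallbacks and sampling caps).
    """

    max_order: int
    rows: dict[StateKey, dict[StateKey, int]] = field(default_factory=dict)
    nodes: tuple[str, ...] = ()
    source_l_max: int = 0

    @property
    def entries(self) -> dict[tuple[StateKey, StateKey], int]:
        return {(s, t): c for s, row in self.rows.items() for t, c in row.items()}

    @property
    def state_index(self) -> list[StateKey]:
        """All states, layer-major and lexicographic within a layer."""
        states = set(self.rows)
        for row in self.rows.values():
            states.update(row)
        return sorted(states)

    @property
    def total_transitions(self) -> int:
        return sum(c for row in self.rows.values() for c in row.values())

    def row_sum(self, state: StateKey) -> int:
        return sum(self.rows.get(state, {}).values())

    def add(self, src: StateKey, dst: StateKey, count: int) -> None:
        row = self.rows.setdefault(src, {})
        row[dst] = row.get(dst, 0) + count


def build_counts(collection: PathCollection, K: int) -> MultiOrderCounts:
    """Accumulate transition counts of the multi-order state sequences.

    Each path contributes its observation count to every consecutive state
    pair of its encoded sequence, so a row total equals the number of times
    its source state was traversed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    counts = MultiOrderCounts(max_order=K)
    for p in collection.paths:
        seq = encode_state_sequence(p, K)
        for src, dst in zip(seq[:-1], seq[1:]):
            counts.add(src, dst, p.count)
    counts.nodes = tuple(sorted(collection.node_set))
    counts.source_l_max = collection.max_length
    return counts


def _possible_successors(
    state: StateKey, topology: ObservedTopology, K: int
) -> list[StateKey]:
    """Successor states allowed by the topology (terminal always allowed)."""
    if state.kind == "initial":
        return [StateKey("tuple", (v,)) for v in topology.nodes]
    if state.kind == "terminal":
        return []
    succ: list[StateKey] = []
    last = state.labels[-1]
    if len(state.labels) < K:
        succ = [StateKey("tuple", state.labels + (w,)) for w in topology.successors(last)]
    else:
        succ = [
            StateKey("tuple", state.labels[1:] + (w,)) for w in topology.successors(last)
        ]
    succ.append(END_STATE)
    return succ


@dataclass
class MultiOrderModel:
    """Row-stochastic multi-order transition matrix T^(K).

    ``probs[s][s']`` is the transition probability; rows are exact
    normalisations of the count rows, and ``row_totals`` retains the count
    mass behind each row (used for count-weighted aggregation in
    prediction).  ``structural_mask`` holds state pairs that are possible
    under the topology but unobserved — zeros that are *estimated*, as
    opposed to structural zeros which are simply absent from the sparse
    support.
    """

    max_order: int
    probs: dict[StateKey, dict[StateKey, float]]
    row_totals: dict[StateKey, int]
    nodes: tuple[str, ...] = ()
    source_l_max: int = 0
    structural_mask: frozenset[tuple[StateKey, StateKey]] = frozenset()

    @property
    def state_index(self) -> list[StateKey]:
        states = set(self.probs)
        for row in self.probs.values():
            states.update(row)
        return sorted(states)

    def row(self, state: StateKey) -> dict[StateKey, float]:
        return self.probs.get(state, {})

    def probability(self, src: StateKey, dst: StateKey) -> float:
        return self.probs.get(src, {}).get(dst, 0.0)


def to_transition_model(
    counts: MultiOrderCounts, topology: ObservedTopology | None = None
) -> MultiOrderModel:
    """Row-normalise A^(K) into the stochastic matrix T^(K).

    When a topology is supplied, the possible-but-unobserved pairs are
    recorded in ``structural_mask``; pairs violating the topology are never
    representable (structural zeros stay exactly zero by sparsity).
    """
    probs: dict[StateKey, dict[StateKey, float]] = {}
    totals: dict[StateKey, int] = {}
    for src, row in counts.rows.items():
        total = sum(row.values())
        totals[src] = total
        probs[src] = {dst: c / total for dst, c in row.items()}
    mask: set[tuple[StateKey, StateKey]] = set()
    if topology is not None:
        for src in counts.rows:
            observed = counts.rows[src]
            for dst in _possible_successors(src, topology, counts.max_order):
                if dst not in observed:
                    mask.add((src, dst))
    return MultiOrderModel(
        max_order=counts.max_order,
        probs=probs,
        row_totals=totals,
        nodes=counts.nodes,
        source_l_max=counts.source_l_max,
        structural_mask=frozenset(mask),
    )


def fit_model(
    collection: PathCollection,
    K: int,
    topology: ObservedTopology | None = None,
) -> MultiOrderModel:
    """Build counts and normalise in one step."""
    return to_transition_model(build_counts(collection, K), topology)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def path_log_probability(model: MultiOrderModel, path: Union[Path, Iterable[str]]) -> float:
    """Natural-log probability of a path under the model (chain rule).

    Sums log transition probabilities along the encoded state sequence.
    Returns ``-inf`` if any factor is zero — including paths through nodes
    the model has never seen — rather than raising.
    """
    seq = encode_state_sequence(path, model.max_order)
    logp = 0.0
    for src, dst in zip(seq[:-1], seq[1:]):
        p = model.probs.get(src, {}).get(dst, 0.0)
        if p <= 0.0:
            return -math.inf
        logp += math.log(p)
    return logp


def collection_log_likelihood(model: MultiOrderModel, collection: PathCollection) -> float:
    """ln L(T^(K) | S): count-weighted sum of path log-probabilities."""
    total = 0.0
    for p in collection.paths:
        lp = path_log_probability(model, p)
        if lp == -math.inf:
            return -math.inf
        total += p.count * lp
    return total


# ---------------------------------------------------------------------------
# degrees of freedom / model complexity
# ---------------------------------------------------------------------------


def adjacency_power_sums(topology: ObservedTopology, K: int) -> list[int]:
    """[sum(A^1), ..., sum(A^K)] with exact integer arithmetic.

    Entry sums of powers of the binary adjacency count walks of each
    length; object dtype keeps Python-int precision on dense graphs where
    these counts overflow 64 bits quickly.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    A = topology.adjacency.astype(object)
    power = A.copy()
    sums = [int(power.sum())]
    for _ in range(2, K + 1):
        power = power @ A
        sums.append(int(power.sum()))
    return sums


def degrees_of_freedom(topology: ObservedTopology, K: int) -> int:
    """d(T^(K)) = |V| + sum_{k=1..K} sum_ij (A^k)_ij - 1.

    One probability per stochastic row is determined by normalisation; the
    remaining possible transitions are free parameters.
    """
    return topology.n_nodes + sum(adjacency_power_sums(topology, K)) - 1


def possible_transitions(topology: ObservedTopology, K: int) -> int:
    """Maximum number N_tau of possible transitions in T^(K).

    |V| start transitions, all walk transitions up to order K, and one
    terminal transition per connected k-tuple state (tuples of different
    lengths are distinct, so the union size is the sum of per-layer walk
    counts, with |V^1| = |V|).
    """
    sums = adjacency_power_sums(topology, K)
    n_tuple_states = topology.n_nodes + sum(sums[: K - 1])
    return topology.n_nodes + sum(sums) + n_tuple_states


def aic_score(
    model: MultiOrderModel,
    collection: PathCollection,
    topology: ObservedTopology,
) -> float:
    """AIC(T^(K)) = 2 d(T^(K)) - 2 ln L(T^(K) | S); +inf on zero likelihood."""
    ll = collection_log_likelihood(model, collection)
    d = degrees_of_freedom(topology, model.max_order)
    if ll == -math.inf:
        return math.inf
    return 2.0 * d - 2.0 * ll


def selection_objective(penalty: int, log_likelihood: float) -> float:
    """The order-selection objective: complexity penalty minus ln-likelihood."""
    return penalty - log_likelihood


# ---------------------------------------------------------------------------
# order selection
# ---------------------------------------------------------------------------


@dataclass
class ModelSelectionTable:
    """Per-order selection diagnostics and the chosen maximum order."""

    orders: list[int]
    penalty: list[int]
    log_likelihood: list[float]
    dof: list[int]
    aic: list[float]
    objective: list[float]
    selected: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "K": self.orders,
                "penalty": self.penalty,
                "log_likelihood": self.log_likelihood,
                "dof": self.dof,
                "aic": self.aic,
                "objective": self.objective,
            }
        )
        df["selected"] = df["K"] == self.selected
        return df

    def __repr__(self) -> str:
        return f"ModelSelectionTable(K_hat={self.selected}, orders={self.orders})"


def select_optimal_order(
    collection: PathCollection,
    K_max: int | None = None,
    topology: ObservedTopology | None = None,
) -> ModelSelectionTable:
    """Choose the maximum order K̂ minimising AIC.

    Evaluates the selection objective (walk-count penalty minus
    log-likelihood) for K = 1..K_max; K_max defaults to min(l_max, 15).
    Since -ln L >= 0 and the penalty is non-decreasing in K, candidates
    whose penalty alone exceeds the best objective found so far cannot win
    and the scan stops there.  Ties break toward the smaller K.  The full
    AIC is computed per row and its argmin asserted to coincide.
    """
    if collection.total_paths == 0:
        raise EmptyCollectionError("cannot select an order for an empty collection")
    if K_max is None:
        K_max = min(collection.max_length, 15)
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if topology is None:
        topology = observed_adjacency(collection)
    sums = adjacency_power_sums(topology, K_max)
    orders: list[int] = []
    penalties: list[int] = []
    lls: list[float] = []
    dofs: list[int] = []
    aics: list[float] = []
    objectives: list[float] = []
    best = math.inf
    for K in range(1, K_max + 1):
        penalty = sum(sums[:K])
        if penalty > best:
            break  # -ln L >= 0 and penalty non-decreasing: no later K can win
        model = fit_model(collection, K)
        ll = collection_log_likelihood(model, collection)
        d = topology.n_nodes + penalty - 1
        obj = selection_objective(penalty, ll)
        orders.append(K)
        penalties.append(penalty)
        lls.append(ll)
        dofs.append(d)
        aics.append(math.inf if ll == -math.inf else 2.0 * d - 2.0 * ll)
        objectives.append(obj)
        best = min(best, obj)
    i_best = int(np.argmin(objectives))  # argmin returns the first (smallest K) on ties
    i_aic = int(np.argmin(aics))
    assert i_best == i_aic, "objective and AIC argmin must agree"
    return ModelSelectionTable(
        orders=orders,
        penalty=penalties,
        log_likelihood=lls,
        dof=dofs,
        aic=aics,
        objective=objectives,
        selected=orders[i_best],
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


# Reserved symbols cannot be node labels, so singleton ["*"] / ["\u2020"]
# lists unambiguously denote the special states in the JSON container.
def _state_to_token(state: StateKey) -> list[str]:
    if state.kind == "initial":
        return [START_SYMBOL]
    if state.kind == "terminal":
        return [END_SYMBOL]
    return list(state.labels)


def _state_from_token(token: list[str]) -> StateKey:
    if token == [START_SYMBOL]:
        return START_STATE
    if token == [END_SYMBOL]:
        return END_STATE
    return StateKey("tuple", tuple(token))


def model_to_json(model: MultiOrderModel, sink: Union[str, PathLike, None] = None) -> str:
    """Serialise a model to a JSON container (sparse triples)."""
    index = model.state_index
    pos = {s: i for i, s in enumerate(index)}
    payload = {
        "max_order": model.max_order,
        "nodes": list(model.nodes),
        "source_l_max": model.source_l_max,
        "states": [_state_to_token(s) for s in index],
        "probabilities": [
            [pos[s], pos[t], p] for s, row in model.probs.items() for t, p in row.items()
        ],
        "row_totals": [[pos[s], c] for s, c in model.row_totals.items()],
    }
    text = json.dumps(payload, ensure_ascii=False, indent=1, sort_keys=True)
    if sink is not None:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def model_from_json(source: Union[str, PathLike]) -> MultiOrderModel:
    """Load a model serialised by :func:`model_to_json`.

    ``source`` may be a filesystem path or a JSON string.
    """
    text: str
    if isinstance(source, PathLike) or (isinstance(source, str) and not source.lstrip().startswith("{")):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)
    payload = json.loads(text)
    states = [_state_from_token(t) for t in payload["states"]]
    probs: dict[StateKey, dict[StateKey, float]] = {}
    for i, j, p in payload["probabilities"]:
        probs.setdefault(states[i], {})[states[j]] = p
    totals = {states[i]: int(c) for i, c in payload["row_totals"]}
    return MultiOrderModel(
        max_order=int(payload["max_order"]),
        probs=probs,
        row_totals=totals,
        nodes=tuple(payload["nodes"]),
        source_l_max=int(payload["source_l_max"]),
    )


def export_matrix_market(model: MultiOrderModel, sink: Union[str, PathLike]) -> None:
    """Write T^(K) as a Matrix Market sparse file plus a state-index sidecar."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    index = model.state_index
    pos = {s: i for i, s in enumerate(index)}
    rows, cols, vals = [], [], []
    for s, row in model.probs.items():
        for t, p in row.items():
            rows.append(pos[s])
            cols.append(pos[t])
            vals.append(p)
    mat = coo_matrix((vals, (rows, cols)), shape=(len(index), len(index)))
    mmwrite(str(sink), mat)
    with open(str(sink) + ".states", "w", encoding="utf-8") as fh:
        for s in index:
            fh.write(str(s) + "\n")
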