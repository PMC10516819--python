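"""Next-element prediction and cross-entropy evaluation.

Given a prefix of nodes traversed by a path, predict the next element —
either the next visited node or path termination (``†``).  The multi-order
model predicts by aggregating the count-weighted rows of every memory
state consistent with the known suffix; baselines cover a node-frequency
predictor (RND), single-order Markov predictors (NET), and an
all-K-order-Markov predictor with longest-context fallback (AKOM).

Prediction quality is scored with the cross-entropy loss in bits over a
weighted set of prefix-target pairs: the weighted mean of
``-log2 q(target | prefix)``, where the per-occurrence prefix weights sum
to one so that each observed target contributes one unit of evidence
regardless of how many prefix lengths were enumerated for it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import pandas as pd

from .model import END_STATE, START_STATE, MultiOrderModel, StateKey
from .paths import END_SYMBOL, PathCollection, PrefixTargetSet

__all__ = [
    "PredictionDistribution",
    "CrossEntropyReport",
    "next_element_distribution",
    "frequency_fallback",
    "cross_entropy_loss",
    "rnd_distribution",
    "FixedOrderPredictor",
    "fixed_order_model",
    "AkomPredictor",
    "akom_distribution",
]

_SUM_TOL = 1e-12


@dataclass
class PredictionDistribution:
    """Probability mass over the next element (node label or ``†``)."""

    mass: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        total = math.fsum(self.mass.values())
        if not self.mass or abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass must sum to 1, got {total!r}")
        if any(p < 0 for p in self.mass.values()):
            raise ValueError("negative probability mass")
        # renormalise exactly once to kill accumulated float error
        self.mass = {k: v / total for k, v in self.mass.items()}

    def prob(self, element: str) -> float:
        return self.mass.get(element, 0.0)

    @property
    def support(self) -> list[str]:
        return sorted(self.mass)

    def top(self, n: int = 1) -> list[tuple[str, float]]:
        return sorted(self.mass.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def _from_weights(weights: dict[str, float], provenance: str) -> PredictionDistribution:
    total = math.fsum(weights.values())
    if total <= 0:
        raise ValueError("empty weight vector")
    return PredictionDistribution({k: v / total for k, v in weights.items() if v > 0}, provenance)


def _project(state: StateKey) -> str:
    """Map a successor state to the predicted element: its last label or †."""
    return END_SYMBOL if state.kind == "terminal" else state.labels[-1]


def frequency_fallback(model: MultiOrderModel) -> PredictionDistribution:
    """Training node-frequency distribution reconstructed from the model.

    Every node visit in the training data corresponds to exactly one
    transition into a tuple state ending in that node, and the number of
    training paths equals the start-row total; tallying incoming count
    mass therefore reproduces the node-frequency (RND) distribution
    without access to the raw collection.
    """
    weights: dict[str, float] = {}
    for src, row in model.probs.items():
        total = model.row_totals[src]
        for dst, p in row.items():
            weights[_project(dst)] = weights.get(_project(dst), 0.0) + p * total
    return _from_weights(weights, "fallback:node-frequency")


def next_element_distribution(
    model: MultiOrderModel,
    prefix: Iterable[str],
    mode: str = "aggregate",
    fallback: PredictionDistribution | None = None,
) -> PredictionDistribution:
    """Predict the next element from a prefix of any length.

    For an empty prefix, the start row projected onto first nodes.  For a
    prefix of length n >= 1 the prefix is truncated to its last
    s = min(n, K) labels and, in ``aggregate`` mode, the count-weighted
    rows of *all* states in layers s..K whose label tuple ends with that
    suffix are summed before projecting successor states onto their last
    label (or ``†``) — a mid-path prefix does not imply the path started s
    steps ago, so every consistent memory state contributes.  ``layer``
    mode restricts to the single layer-s row.  An empty aggregate (unseen
    suffix or unknown labels) yields the fallback distribution, by default
    the training node-frequency distribution.
    """
    if mode not in ("aggregate", "layer"):
        raise ValueError(f"unknown mode {mode!r}")
    prefix = tuple(prefix)
    K = model.max_order
    if len(prefix) == 0:
        row = model.probs.get(START_STATE, {})
        if row:
            total = model.row_totals[START_STATE]
            return _from_weights(
                {_project(dst): p * total for dst, p in row.items()}, "start-row"
            )
    else:
        s = min(len(prefix), K)
        suffix = prefix[-s:]
        weights: dict[str, float] = {}
        matched = []
        for src, row in model.probs.items():
            if src.kind != "tuple":
                continue
            k = len(src.labels)
            if k < s or (mode == "layer" and k != s):
                continue
            if src.labels[-s:] != suffix:
                continue
            matched.append(src)
            total = model.row_totals[src]
            for dst, p in row.items():
                el = _project(dst)
                weights[el] = weights.get(el, 0.0) + p * total
        if weights:
            prov = f"{mode}:{len(matched)} state(s), layers {s}..{K}"
            return _from_weights(weights, prov)
    if fallback is None:
        fallback = frequency_fallback(model)
    return fallback


# ---------------------------------------------------------------------------
# cross-entropy
# ---------------------------------------------------------------------------


@dataclass
class CrossEntropyReport:
    """Weighted cross-entropy of a predictor over prefix-target pairs."""

    total_bits: float
    per_prefix_length: dict[int, float]
    n_items: int
    clip_events: int
    floor: float
    items_per_length: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.per_prefix_length)
        return pd.DataFrame(
            {
                "prefix_length": lengths,
                "items": [self.items_per_length.get(n, 0) for n in lengths],
                "bits": [self.per_prefix_length[n] for n in lengths],
            }
        )

    def to_dict(self) -> dict:
        return {
            "total_bits": self.total_bits,
            "per_prefix_length": {str(k): v for k, v in sorted(self.per_prefix_length.items())},
            "n_items": self.n_items,
            "clip_events": self.clip_events,
            "floor": self.floor,
        }


Predictor = Callable[[tuple[str, ...]], PredictionDistribution]


def cross_entropy_loss(
    predictor: Predictor,
    items: PrefixTargetSet,
    floor: float = 2.0 ** -32,
) -> CrossEntropyReport:
    """Weighted mean surprisal, in bits, of the true targets.

    ``total_bits = sum_i w_i * (-log2 max(q_i, floor)) / sum_i w_i`` where
    q_i is the probability the predictor assigns to item i's target given
    its prefix.  Zero (or sub-floor) probabilities are clipped at ``floor``
    and the number of clip events reported — never silently absorbed.  A
    per-prefix-length breakdown accompanies the total.
    """
    if not (0.0 < floor < 1.0):
        raise ValueError("floor must lie in (0, 1)")
    if len(items) == 0:
        raise ValueError("empty prefix-target set")
    cache: dict[tuple[str, ...], PredictionDistribution] = {}
    num = 0.0
    den = 0.0
    clip = 0
    num_by_n: dict[int, float] = {}
    den_by_n: dict[int, float] = {}
    cnt_by_n: dict[int, int] = {}
    for it in items:
        dist = cache.get(it.prefix)
        if dist is None:
            dist = predictor(it.prefix)
            cache[it.prefix] = dist
        q = dist.prob(it.target)
        if q < floor:
            q = floor
            clip += 1
        surprisal = -math.log2(q)
        n = len(it.prefix)
        num += it.weight * surprisal
        den += it.weight
        num_by_n[n] = num_by_n.get(n, 0.0) + it.weight * surprisal
        den_by_n[n] = den_by_n.get(n, 0.0) + it.weight
        cnt_by_n[n] = cnt_by_n.get(n, 0) + 1
    per = {n: num_by_n[n] / den_by_n[n] for n in num_by_n}
    return CrossEntropyReport(
        total_bits=num / den,
        per_prefix_length=per,
        n_items=len(items),
        clip_events=clip,
        floor=floor,
        items_per_length=cnt_by_n,
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def rnd_distribution(train: PathCollection) -> PredictionDistribution:
    """Prefix-independent node-frequency baseline.

    Mass proportional to node occurrence counts in the training data, with
    the terminal marker weighted by the number of training paths (every
    path terminates exactly once).
    """
    if train.total_paths == 0:
        raise ValueError("empty training collection")
    weights: dict[str, float] = {}
    for p in train.paths:
        for v in p.nodes:
            weights[v] = weights.get(v, 0.0) + p.count
    weights[END_SYMBOL] = float(train.total_paths)
    return _from_weights(weights, "rnd:node-frequency")


class FixedOrderPredictor:
    """Single-order Markov predictor (NET baseline).

    Context tables are sliding-window subpath counts of length k, with
    termination counted from each path's final k nodes — the analogue of
    the multi-order model's layer k.  Prefixes shorter than k, and unseen
    contexts, fall back to the node-frequency distribution.
    """

    def __init__(self, train: PathCollection, k: int) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._contexts: dict[tuple[str, ...], dict[str, int]] = {}
        for p in train.paths:
            nodes = p.nodes
            l = len(nodes)
            for i in range(k, l):
                ctx = nodes[i - k : i]
                row = self._contexts.setdefault(ctx, {})
                row[nodes[i]] = row.get(nodes[i], 0) + p.count
            if l >= k:
                ctx = nodes[l - k :]
                row = self._contexts.setdefault(ctx, {})
                row[END_SYMBOL] = row.get(END_SYMBOL, 0) + p.count
        self._fallback = rnd_distribution(train)

    def context(self, ctx: tuple[str, ...]) -> dict[str, int] | None:
        return self._contexts.get(tuple(ctx))

    def __call__(self, prefix: Iterable[str]) -> PredictionDistribution:
        prefix = tuple(prefix)
        if len(prefix) < self.k:
            return self._fallback
        row = self._contexts.get(prefix[-self.k :])
        if not row:
            return self._fallback
        return _from_weights(dict(row), f"net:order-{self.k}")


def fixed_order_model(train: PathCollection, k: int) -> FixedOrderPredictor:
    """Build the order-k Markov (NET) predictor."""
    return FixedOrderPredictor(train, k)


class AkomPredictor:
    """All-K-order Markov predictor with longest-context fallback.

    Keeps context tables for every order 1..k_max; a query uses the
    largest k <= min(k_max, prefix length) whose context was observed in
    training, falling back to the node-frequency distribution when no
    context matches (including the empty prefix).
    """

    def __init__(self, train: PathCollection, k_max: int) -> None:
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        self.k_max = k_max
        self._orders = [FixedOrderPredictor(train, k) for k in range(1, k_max + 1)]
        self._fallback = rnd_distribution(train)

    def __call__(self, prefix: Iterable[str]) -> PredictionDistribution:
        prefix = tuple(prefix)
        for k in range(min(self.k_max, len(prefix)), 0, -1):
            row = self._orders[k - 1].context(prefix[-k:])
            if row:
                return _from_weights(dict(row), f"akom:order-{k}")
        return self._fallback


def akom_distribution(
    train: PathCollection, k_max: int, prefix: Iterable[str]
) -> PredictionDistribution:
    """One-shot AKOM query (builds the tables; use AkomPredictor for loops)."""
    return AkomPredictor(train, k_max)(prefix)
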