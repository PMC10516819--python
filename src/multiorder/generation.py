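"""Generative path sampling and out-of-sample ranking evaluation.

A fitted multi-order model is a generative process: start at ``*``, draw
successive transitions from the current state's row, and stop when the
terminal state ``†`` is drawn.  Sampling many paths yields a surrogate
collection whose frequency ranking can be compared against a held-out
validation set — via top-N ROC/AUC (treating "is this path among the top
fraction of validation paths" as a binary label scored by generated
frequency) and via Kendall's τ-b rank correlation over the union of
unique paths, scoring absent paths 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve

from .model import END_STATE, START_STATE, MultiOrderModel, StateKey
from .paths import Path, PathCollection

__all__ = [
    "PathLengthCapError",
    "GeneratedSet",
    "RankingEvaluation",
    "sample_path",
    "sample_collection",
    "resampling_baseline",
    "roc_auc_top_n",
    "kendall_tau_frequencies",
]


class PathLengthCapError(RuntimeError):
    """A sampled walk exceeded the length cap before reaching the terminal state."""


@dataclass
class GeneratedSet:
    """A multiset of sampled paths S' with sampling provenance."""

    paths: PathCollection
    sample_size: int
    seed: int | None
    n_capped: int = 0

    def __post_init__(self) -> None:
        if self.paths.total_paths != self.sample_size:
            raise ValueError("sample_size must equal the total generated frequency")


@dataclass
class RankingEvaluation:
    """Top-N ROC/AUC and rank correlation of generated vs validation frequencies."""

    auc: float
    roc_points: list[tuple[float, float]]
    tau: float
    positives_fraction: float
    n_universe: int = 0
    n_positives: int = 0


class _RowSampler:
    """Per-row cumulative-probability cache for O(log d) categorical draws."""

    def __init__(self, model: MultiOrderModel) -> None:
        self._model = model
        self._cache: dict[StateKey, tuple[list[StateKey], np.ndarray]] = {}

    def draw(self, state: StateKey, rng: np.random.Generator) -> StateKey:
        entry = self._cache.get(state)
        if entry is None:
            row = self._model.probs.get(state)
            if not row:
                raise PathLengthCapError(f"state {state} has no outgoing transitions")
            targets = sorted(row)
            cum = np.cumsum([row[t] for t in targets])
            cum[-1] = 1.0  # guard float round-off at the top end
            entry = (targets, cum)
            self._cache[state] = entry
        targets, cum = entry
        return targets[int(np.searchsorted(cum, rng.random(), side="right"))]


def _default_cap(model: MultiOrderModel) -> int:
    base = model.source_l_max if model.source_l_max else model.max_order
    return 10 * base


def sample_path(
    model: MultiOrderModel,
    rng_seed: int | np.random.Generator,
    max_length: int | None = None,
    _sampler: _RowSampler | None = None,
) -> Path:
    """Draw one path: walk from ``*`` until ``†`` is drawn.

    Raises :class:`PathLengthCapError` if the walk exceeds ``max_length``
    nodes (default 10x the longest training path) without terminating.
    """
    if START_STATE not in model.probs or not model.probs[START_STATE]:
        raise ValueError("model has no start-state row; cannot generate")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    cap = max_length if max_length is not None else _default_cap(model)
    sampler = _sampler if _sampler is not None else _RowSampler(model)
    nodes: list[str] = []
    state = START_STATE
    while True:
        nxt = sampler.draw(state, rng)
        if nxt == END_STATE:
            return Path(tuple(nodes))
        nodes.append(nxt.labels[-1])
        if len(nodes) > cap:
            raise PathLengthCapError(f"walk exceeded length cap {cap}")
        state = nxt


def sample_collection(
    model: MultiOrderModel,
    n: int,
    seed: int,
    max_length: int | None = None,
) -> GeneratedSet:
    """Draw n independent paths; capped walks are discarded and counted.

    Reproducible under a fixed seed.  Raises if every draw hits the cap.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = _RowSampler(model)
    out = PathCollection()
    capped = 0
    for _ in range(n):
        try:
            p = sample_path(model, rng, max_length=max_length, _sampler=sampler)
        except PathLengthCapError:
            capped += 1
            continue
        out.add(p.nodes)
    if out.total_paths == 0:
        raise PathLengthCapError("every sampled walk hit the length cap")
    return GeneratedSet(paths=out, sample_size=out.total_paths, seed=seed, n_capped=capped)


def resampling_baseline(train: PathCollection, n: int, seed: int) -> GeneratedSet:
    """Model-less baseline: resample n paths from training frequencies.

    Draws with replacement, proportional to observed counts — the
    prediction one would make assuming validation frequencies equal
    training frequencies.
    """
    if train.total_paths == 0:
        raise ValueError("empty training collection")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    items = sorted(train.counts.items())
    probs = np.array([c for _, c in items], dtype=float)
    probs /= probs.sum()
    draws = rng.multinomial(n, probs)
    out = PathCollection()
    for (nodes, _), d in zip(items, draws):
        if d:
            out.add(nodes, int(d))
    return GeneratedSet(paths=out, sample_size=n, seed=seed)


# ---------------------------------------------------------------------------
# ranking evaluation
# ---------------------------------------------------------------------------


def _universe(generated: GeneratedSet, validation: PathCollection):
    gen = generated.paths.counts
    val = validation.counts
    universe = sorted(set(gen) | set(val))
    scores = np.array([gen.get(p, 0) for p in universe], dtype=float)
    val_freq = np.array([val.get(p, 0) for p in universe], dtype=float)
    return universe, scores, val_freq


def roc_auc_top_n(
    generated: GeneratedSet,
    validation: PathCollection,
    top_fraction: float = 0.1,
) -> RankingEvaluation:
    """Score the top-N prediction of frequent validation paths.

    Positives are the top ``ceil(top_fraction * #unique validation paths)``
    validation paths by frequency (ties broken stably by canonical path
    order); every path in the union of unique generated and validation
    paths is scored by its generated frequency (0 if never generated).
    Sweeping the discrimination threshold N yields the ROC; AUC by the
    trapezoid rule.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie in (0, 1)")
    if generated.paths.total_paths == 0 or validation.total_paths == 0:
        raise ValueError("empty input")
    universe, scores, _ = _universe(generated, validation)
    val = validation.counts
    n_pos = math.ceil(top_fraction * len(val))
    ranked = sorted(val, key=lambda p: (-val[p], p))
    positives = set(ranked[:n_pos])
    labels = np.array([1 if p in positives else 0 for p in universe])
    if labels.min() == labels.max():
        raise ValueError("degenerate labelling: only one class present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc_value = float(_sk_auc(fpr, tpr))
    try:
        tau = kendall_tau_frequencies(generated, validation)
    except ValueError:
        tau = math.nan  # all-tied scores: ROC is still defined, tau is not
    return RankingEvaluation(
        auc=auc_value,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        tau=tau,
        positives_fraction=n_pos / len(universe),
        n_universe=len(universe),
        n_positives=n_pos,
    )


def kendall_tau_frequencies(
    generated: GeneratedSet, validation: PathCollection
) -> float:
    """Kendall τ-b between generated and validation frequency rankings.

    Computed over the union of unique paths with absent paths scored 0;
    τ-b handles the pervasive ties among small integer frequencies.
    """
    universe, scores, val_freq = _universe(generated, validation)
    if len(universe) < 2:
        raise ValueError("need at least two unique paths")
    tau = stats.kendalltau(scores, val_freq, variant="b").statistic
    if math.isnan(tau):
        raise ValueError("rank correlation undefined: all frequencies tied")
    return float(tau)
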