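"""Independent brute-force oracles for cross-checking the implementation.

Everything here is re-derived from first principles with deliberately
naive algorithms and exact rational arithmetic, sharing no code with the
package's fitting/likelihood/selection paths.
"""
from __future__ import annotations

import math
from fractions import Fraction

from multiorder.paths import PathCollection


def brute_state_sequence(nodes: tuple[str, ...], K: int) -> list:
    """Naive re-derivation of the multi-order state sequence.

    States are encoded as plain strings/tuples: "*" start, "+" terminal,
    else a tuple of labels — intentionally a different representation from
    the package's StateKey.
    """
    seq: list = ["*"]
    for end in range(1, len(nodes) + 1):
        start = max(0, end - K)
        seq.append(tuple(nodes[start:end]))
    seq.append("+")
    return seq


def brute_transition_counts(collection: PathCollection, K: int) -> dict:
    """Explicit instance-expanded transition tally."""
    tally: dict = {}
    for p in collection.paths:
        for _ in range(p.count):  # expand instances one by one, on purpose
            seq = brute_state_sequence(p.nodes, K)
            for a, b in zip(seq[:-1], seq[1:]):
                tally[(a, b)] = tally.get((a, b), 0) + 1
    return tally


def brute_path_probability(
    collection: PathCollection, K: int, nodes: tuple[str, ...]
) -> Fraction:
    """Exact rational path probability under the fitted multi-order chain."""
    tally = brute_transition_counts(collection, K)
    row_sums: dict = {}
    for (a, _), c in tally.items():
        row_sums[a] = row_sums.get(a, 0) + c
    prob = Fraction(1)
    seq = brute_state_sequence(nodes, K)
    for a, b in zip(seq[:-1], seq[1:]):
        c = tally.get((a, b), 0)
        if c == 0:
            return Fraction(0)
        prob *= Fraction(c, row_sums[a])
    return prob


def brute_log_likelihood(collection: PathCollection, K: int) -> float:
    """Count-weighted log-probability sum, via exact rationals."""
    total = 0.0
    for p in collection.paths:
        prob = brute_path_probability(collection, K, p.nodes)
        if prob == 0:
            return -math.inf
        total += p.count * math.log(prob)
    return total


def brute_walk_count(edges: set[tuple[str, str]], nodes: list[str], k: int) -> int:
    """Number of distinct walks of k edges, by explicit enumeration."""
    walks = [(v,) for v in nodes]
    for _ in range(k):
        walks = [w + (x,) for w in walks for x in nodes if (w[-1], x) in edges]
    return len(walks)


def brute_degrees_of_freedom(
    edges: set[tuple[str, str]], nodes: list[str], K: int
) -> int:
    """|V| + (number of walks with 1..K edges) - 1, by enumeration."""
    return len(nodes) + sum(brute_walk_count(edges, nodes, k) for k in range(1, K + 1)) - 1


def brute_selection(collection: PathCollection, K_max: int) -> int:
    """Argmin over K of (walk penalty - log-likelihood), smallest K on ties."""
    edges = {pair for pair, _ in collection.transitions()}
    nodes = sorted(collection.node_set)
    best_K, best_obj = None, math.inf
    for K in range(1, K_max + 1):
        penalty = sum(brute_walk_count(edges, nodes, k) for k in range(1, K + 1))
        obj = penalty - brute_log_likelihood(collection, K)
        if obj < best_obj:
            best_K, best_obj = K, obj
    return best_K
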