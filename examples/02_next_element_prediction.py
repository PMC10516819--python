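"""Predict the next element of a partial path — or its termination.

Fits the order-2 model on the toy collection and queries it with prefixes
of different lengths, then scores model vs baselines by cross-entropy on
the collection's own prefix-target pairs (lower bits = better).
"""
from multiorder import (
    AkomPredictor,
    cross_entropy_loss,
    extract_prefix_targets,
    fit_model,
    fixed_order_model,
    next_element_distribution,
    rnd_distribution,
    toy_collection,
)

toy = toy_collection()
model = fit_model(toy, 2)

for prefix in [(), ("C",), ("A", "C"), ("D", "E")]:
    dist = next_element_distribution(model, prefix)
    pretty = {el: round(p, 3) for el, p in sorted(dist.mass.items())}
    print(f"prefix {prefix!r:>12} -> {pretty}")
print(
    "\nThe empty prefix returns the start distribution; (C) aggregates the"
    "\nmemory states (A,C) and (B,C); the dagger entry is the probability"
    "\nthat the path ends here.\n"
)

items = extract_prefix_targets(toy, max_prefix=6)
predictors = {
    "multi-order (K=2)": lambda pfx: next_element_distribution(model, pfx),
    "node frequency (RND)": (lambda d: (lambda pfx: d))(rnd_distribution(toy)),
    "order-1 Markov (NET)": fixed_order_model(toy, 1),
    "all-2-order (AKOM)": AkomPredictor(toy, 2),
}
print(f"Cross-entropy over {len(items)} prefix-target pairs:")
for name, pred in predictors.items():
    report = cross_entropy_loss(pred, items)
    print(f"  {name:22s} {report.total_bits:6.3f} bits")
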