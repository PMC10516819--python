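"""Generate full unseen paths and score the frequency ranking.

A planted order-2 process on a random 8-node digraph plays the role of
the real system.  From a small 'survey' of 100 observed paths we fit a
multi-order model, generate 10,000 surrogate paths, and ask how well their
frequency ranking predicts the top-10% most frequent paths in a large
validation sample — compared against simply resampling the training
frequencies.
"""
from multiorder import (
    fit_model,
    planted_model,
    random_planted_model,
    resampling_baseline,
    roc_auc_top_n,
    sample_collection,
    select_optimal_order,
)

spec = random_planted_model(n_nodes=8, out_degree=2, order=2, seed=77, end_prob=0.3)
truth = planted_model(spec)

validation = sample_collection(truth, 2000, seed=1).paths
train = sample_collection(truth, 100, seed=2).paths
print(f"training: {train}")
print(f"validation: {validation}")

K = select_optimal_order(train, K_max=3).selected
model = fit_model(train, K)
generated = sample_collection(model, 10_000, seed=3)
baseline = resampling_baseline(train, 10_000, seed=3)

ev_model = roc_auc_top_n(generated, validation, top_fraction=0.1)
ev_base = roc_auc_top_n(baseline, validation, top_fraction=0.1)
print(f"\nselected K = {K}")
print(f"model     AUC = {ev_model.auc:.3f}   Kendall tau = {ev_model.tau:.3f}")
print(f"resample  AUC = {ev_base.auc:.3f}   Kendall tau = {ev_base.tau:.3f}")
print(
    "\nThe model generalises: it generates plausible paths never observed in"
    "\nthe 100 training paths, so it ranks frequent validation paths better"
    "\nthan resampling training frequencies (AUC 0.5 = uninformative)."
)
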