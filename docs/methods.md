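# Methods

## Model

A collection of paths is a multiset S = {t₁, …, t_m} of node sequences on
a directed graph G(V, E); path lengths l_i vary and l_max denotes the
longest. The multi-order model of maximum order K is a Markov chain on an
extended state space: the virtual initial state `*`, tuple states
(v₁, …, v_k) for k = 1..K whose consecutive labels are edges of G, and the
absorbing terminal state `†`. A path of length l is encoded as the state
sequence `* → (v₁) → (v₁,v₂) → … → †`: the memory grows by one node per
transition up to length K and then slides. The encoding has l + 2 states
and l + 1 transitions; the path's probability is the product of the l + 1
row-stochastic transition probabilities, so start-node choice and
termination are modelled explicitly rather than conditioned away.

Counts A⁽ᴷ⁾ are accumulated per encoded transition and the transition
matrix T⁽ᴷ⁾ is the exact row normalisation. Transitions impossible under
the binary first-order topology 𝒜 (where 𝒜_vw = 1 iff v→w occurs in the
data, or in a user-declared edge list) are structural zeros and are simply
absent from the sparse support; possible-but-unobserved pairs are recorded
separately in `structural_mask` because they, unlike structural zeros, are
estimated (at zero) and therefore count toward model complexity.

Degrees of freedom: d(T⁽ᴷ⁾) = |V| + Σ_{k=1..K} Σ_ij (𝒜ᵏ)_ij − 1. The walk
counts Σ(𝒜ᵏ) are computed with arbitrary-precision integer matrices
(numpy object dtype): on dense graphs they overflow 64-bit arithmetic at
modest K. The number of possible transitions N_τ additionally counts the
|V| start transitions and one terminal transition per connected tuple
state; tuples of different lengths are distinct, so the union size is the
sum of per-layer walk counts.

## Order selection

AIC(T⁽ᴷ⁾) = 2 d(T⁽ᴷ⁾) − 2 ln L(T⁽ᴷ⁾|S) is minimised over K = 1..K_max.
Because d differs from the walk penalty Σ_{k≤K}Σ(𝒜ᵏ) only by the constant
|V| − 1, the argmin equals that of `penalty − ln L`; the implementation
computes both and asserts agreement. Since −ln L ≥ 0 and the penalty is
non-decreasing in K, any K whose penalty alone exceeds the best objective
so far cannot win and the scan stops there. Ties break toward the smaller
K (parsimony). K_max defaults to min(l_max, 15): beyond l_max the model is
a lossless representation of S (every path probability equals its
empirical frequency count/m) and the likelihood cannot improve further.
Natural logarithms are used throughout likelihood and AIC; cross-entropy
is reported in bits.

Two degenerate-input rules: paths shorter than K follow the same encoding
schema (the growing prefixes simply stop before reaching length K), and a
path containing a transition or node the model never saw has probability
zero — `path_log_probability` returns −inf rather than raising, and the
AIC becomes +inf.

AIC retains a constant non-vanishing over-selection probability (a
spurious likelihood gain of order χ²/2 can exceed a small penalty
increment), so order recovery on data from a planted process is asserted
as a high-frequency property over many sampled replications, never as a
per-seed certainty.

## Next-element prediction

For a prefix of n visited nodes the model predicts the next element —
a node or `†`. The prefix is truncated to its last s = min(n, K) labels.
A layer-s row alone would assert "the path started exactly s steps ago",
which a mid-path prefix does not imply, so by default the count-weighted
rows of *all* tuple states in layers s..K ending with the suffix are
summed, successor states are projected onto their last label (or `†`),
and the aggregate is normalised. For n ≥ K this degenerates to the unique
layer-K row. A strict `layer` mode (the single layer-s row) is available.
The empty prefix returns the start distribution.

When the aggregate is empty (unseen suffix or unknown labels) a fallback
distribution is returned: the training node-frequency distribution,
reconstructed exactly from the fitted model — each node visit corresponds
to one incoming transition to a tuple state ending in that node, and the
start-row total equals the number of training paths, which weights `†`.
This choice keeps prediction total (no exceptions at query time) and
matches the node-frequency baseline's semantics for unseen contexts.

Evaluation enumerates, for every target occurrence in the validation
paths (each interior node and the terminal marker), all prefixes of
lengths 1..min(available, 6 by default); the weights of one occurrence's
prefixes sum to its observation count, so each observed target contributes
one unit of evidence regardless of how many prefix lengths exist for it.
The reported loss is the weighted mean of −log₂ q(target|prefix),
equivalently the sample-weighted multi-class log-loss in bits; a
per-prefix-length breakdown accompanies the total. Probabilities below a
floor (default 2⁻³²) are clipped and the clip events counted in the
report — never silently absorbed. The floor keeps losses finite when a
model assigns zero to a realised target; its default is small enough that
a single clip dominates a report, making such events visible.

Baselines: RND (prefix-independent node-frequency distribution, `†`
weighted by the number of paths), NET (a single order-k Markov predictor
with sliding-window context counts and termination from each path's final
k nodes; prefixes shorter than k fall back to RND), and AKOM (context
tables for all orders 1..k_max, queried longest-context-first, RND
fallback). An `include_empty_prefix` flag extends the enumeration with
n = 0 items predicted from the start distribution.

## Generation and ranking evaluation

Sampling walks from `*` row by row until `†` is drawn, using cached
per-row cumulative probabilities; a cap of 10·l_max(training) guards
against non-terminating pathological models, and capped draws are
discarded and reported, never silently kept. Sampled paths are
automatically topology-consistent because structural zeros carry no mass.

Out-of-sample ranking: the candidate universe is the union of unique
generated and validation paths; a path's score is its generated frequency
(0 if never generated). Positives are the top ⌈fraction · #unique
validation paths⌉ validation paths by frequency, ties broken stably by
canonical path order. ROC and trapezoid AUC come from scikit-learn;
Kendall τ uses the τ-b variant (scipy) because small integer frequencies
tie pervasively. An all-tied score vector leaves τ undefined (error from
the τ function; NaN inside the combined ROC evaluation, where the ROC
itself is still meaningful). The model-less baseline resamples paths from
training frequencies with replacement (a multinomial draw).

## Synthetic data

The toy system: six nodes A–F, edges A→C, B→C, C→D, D→E, D→F, and five
paths A–C, A–C–D–E, A–C–D–F, B–C–D–E, B–C–D–F with configurable
frequencies. Equal frequencies make termination independent of the start
node (true order 2); concentrating mass on A–C–D–E and B–C–D–F plants a
start–terminal dependency (true order 3). The default frequency vector is
(10, 10, 10, 10, 10) and the dependency instance used in tests is
(10, 50, 0, 0, 50).

Planted models are explicit stochastic rows over the extended state
space, either taken from a model fitted to a reference collection (the
toy instances above) or drawn randomly: `random_planted_model` builds a
random digraph with fixed out-degree and Dirichlet rows with a reserved
termination probability (default 0.2) at every tuple state, so walks
terminate almost surely and every planted row reaches `†`.

What the generators emulate: variable path lengths, topology constraints,
explicit start/end statistics, and genuine higher-order dependence of
known order. What they do not: the heavy-tailed path-length and node-
degree distributions, non-stationarity, and measurement noise of real
clickstream or transit data — so passing recovery tests demonstrates
correctness of the machinery under the model's own assumptions, not
field performance on empirical data.

Experiment sizes used in the test suite: order recovery uses 100
replications of 1000 sampled paths (detection is asserted in ≥ 95% of
them); sampling consistency uses a χ² goodness-of-fit at 10⁴ draws; the
out-of-sample experiment uses a planted order-2 process on an 8-node
digraph with 100 training paths, 2000 validation paths and 10⁴ generated
paths over 50 replications, a small-training/large-validation regime in
which generative ranking is expected to beat frequency resampling in
≥ 90% of replications. These sizes are the package's own choice of a
desk-scale experimental design with stable statistics.

## Numerical choices and limitations

- Row normalisation is exact (`count/total` per entry); row sums are
  asserted to 1e−12 in tests.
- State ordering is layer-major and lexicographic within a layer, `*`
  first and `†` last, making serialised layouts reproducible.
- The train/validation split assigns path *instances* (multiplicity),
  via a multivariate hypergeometric draw, so frequencies divide naturally.
- Serialisation: a JSON container (state index + sparse triples for
  probabilities and row totals) and Matrix Market export with a
  state-index sidecar.
- Limitations: no smoothing/pseudo-counts inside the fitted model
  (regularisation lives only in the evaluation floor); no streaming
  parsing; no temporal timestamps; fitting is single-threaded; the state
  space grows with the number of distinct walk tuples, so very dense
  topologies at large K are memory-hungry.
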