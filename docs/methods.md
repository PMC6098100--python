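# Methods

## Entropy engine

The walk model on a network with adjacency **A** is the row-normalized Markov
chain p_ij = w_ij / Σ_m w_im.  Three conventions are under-determined by the
descriptor's usual presentation and fixed here explicitly:

* **Initial distribution** ⁰p: uniform 1/n.  This is the minimal-assumption
  choice; any other start vector would need per-network side information.
  It matters: the registry of reference topologies ships with descriptor
  values printed by the MI-NODES tool, and those values are *not* reproducible
  under a uniform start in base 2 or base e — MI-NODES evidently used an
  undocumented initial-probability/normalization convention.  The package
  therefore treats printed registry values strictly as fixtures
  (`printed_descriptors`) and computes its own convention alongside
  (`descriptors`); pipelines choose via `build_mt(descriptor_source=...)`.
  Everything downstream is base- and convention-consistent, so the choice
  rescales features rather than changing the method.
* **Log base**: 2 (bits) by default, natural log via `log_base=e`.
* **Isolated nodes**: the transition row gets a self-loop (p_ii = 1) so Π
  stays stochastic without dropping nodes — web node counts must be stable
  because features of one node are compared across networks.
* **Node entropy**: Sh_kj is node j's contribution −ᵏp_j log ᵏp_j inside the
  graph entropy, so Sh_k(G) = Σ_j Sh_kj decomposes exactly.  The alternative
  reading — the entropy of row j of Π^k — is implemented behind
  `node_entropies(per_row=True)` for comparison but is not the default.
* **k range**: 0..5.  k indexes topological distance of interaction; beyond
  5 the walk is near-stationary on graphs of the sizes considered.

Correctness is anchored to an independent oracle: on every graph with ≤ 6
nodes the matrix-power walk distribution is checked against explicit
enumeration of all length-k walks, and closed forms (Sh_k(G) = log₂ n on
regular connected graphs, uniform stationarity, the log₂ n upper bound) are
asserted exactly.

## Topology descriptors

A feed-forward topology is rendered as an undirected layered graph: complete
bipartite connection between consecutive layers, no bias neurons, no skip
connections, no intra-layer edges.  Direction is dropped deliberately — the
descriptors are walk-based on symmetric adjacency, and the information being
captured is connectivity shape, not signal flow.  The topology descriptor
annSh_k is the mean node entropy of that graph (sum over neurons / neuron
count), making topologies of different sizes comparable.

Parsing accepts the full "KIND in:l1-...-lm:out" notation (the in/out
annotations are validated against the first/last layer) and the hidden-layer
notation used for deep nets ("n-n*2-n" with n substituted; supported tokens:
integers, n, n*2, n:2, n:4 with floor division).  Whether the "in:" count of
the original tool included a bias unit is unknowable from the notation; we
assume not.

## Dataset construction

The pair table (bsi) samples linked and unlinked species pairs uniformly
without replacement, per web, balanced 1:1 by default — the published
baseline's near-balanced confusion totals imply near-balanced classes, and
the original sampling ratio is not stated.  In bipartite webs node i always
comes from the row guild and j from the column guild, fixing the sign of
ΔSh; unipartite pairs are oriented by lower index so no unordered pair
appears twice.  Features are computed from the pair's own network; the ΔSh
columns are exact differences by construction (asserted in tests).

The meta-table (mt) has one row per (pair, base classifier); its label is 1
iff the classifier's score, thresholded at 0.5, equals A_ij.  The threshold
is a choice — the source description says only "correctly predicts" — and is
exposed as a parameter.  Row count is |bsi| × |pool| identically.

Base classifiers map topology → estimator: hidden-layer topologies become
multilayer perceptrons with those hidden sizes (logistic activation, Adam,
seeded), linear topologies become logistic regression.  Whether the original
base nets were trained on all pairs or a split is not stated; the pool here
trains on a 75/25 stratified split's training side and predicts the full
table.  A non-converged base classifier is kept (with a warning): its
predictions are still defined, and a weak base classifier is itself
informative at the meta level.

Splitting is stratified on (label × network) with largest-remainder
allocation: per-stratum train counts deviate from the exact share by < 1 row
while the global train count equals round(fraction·N); singleton strata go to
the training side.

## The meta-models

`fit_lda` fits the 24-feature linear discriminant with equal priors
(configurable).  The ΔSh features are exact linear combinations of the node
features, so the within-class covariance of the full feature set is singular
by construction; the fit then uses a ridge-regularized (shrinkage 1e-3)
solver with a warning, and Wilks' Λ / Bartlett's χ² = −(n−1−(p+g)/2)·ln Λ are
computed on the full-rank principal subspace of the total scatter, with the
effective dimension as degrees of freedom.  The decision threshold is S ≥ 0,
the standard two-group boundary for a centered discriminant.

The classifier menu provides the nonlinear families behind one
fit/predict_score contract: LDA, logistic regression, Gaussian naive Bayes,
a decision tree (decision-table surrogate), a 500-tree random forest,
bagging over trees and over small perceptrons, AdaBoost, perceptrons with
one (13) and two (18, 9) hidden layers, and a deep fully-connected net with
hidden shape n–2n–n (default n = 200, tanh, Adam).  Hyperparameters follow
the original study's settings where a scikit-learn equivalent exists, with
two deliberate substitutions: boosting uses tree weak learners (scikit-learn
perceptrons do not accept the sample weights boosting requires), and the
deep net regularizes with L2 weight decay in place of dropout, which
scikit-learn's perceptron does not implement.  Behavioral equivalence with
the original Weka/Keras configurations is not promised.  The deep net's
default budget is 50 epochs, configurable, for desk-scale runs.

An optional greedy forward selection is *not* provided: the published
five-feature model plausibly came from stepwise selection, but the procedure
is undescribed and any reimplementation would imply an equivalence that
cannot be checked.  The frozen coefficients are shipped instead.

## Synthetic webs

The generator emulates three properties of empirical interaction webs:
bipartite structure, sparse connectance, and degree skew.  Link probability
for (i, j) is proportional to u_i·v_j with log-normal propensities whose
log-sd is the `heterogeneity` parameter (0 = bipartite Erdős–Rényi), scaled
to the target connectance and clipped at 1; whole webs are resampled (cap
200) until no species is isolated.  Defaults — 12×12 species per guild with
±30 % size jitter, connectance 0.25, heterogeneity 0.4 — sit inside the range
reported for empirical pollination/parasitism webs while keeping the
no-isolation constraint comfortably feasible; note the conditioning slightly
inflates realized connectance above the nominal target.

Not emulated: nestedness or modularity beyond what degree skew induces,
phylogenetic signal, sampling effort biases, weighted interaction strengths.
Consequently, passing tests demonstrate the machinery end to end and the
meta-layer's ability to separate strong from weak classifiers under known
conditions; they do not certify performance on real archive data, which is
richer in exploitable structure.

`NoisyOracleClassifier` is a synthetic diagnostic implementation of the base
classifier contract with a dialed-in accuracy (memorized training rows,
labels flipped at rate 1−accuracy); it exists to test the meta-learning
layer under controlled conditions and models nothing.

## Problem sizes

Desk-scale runs use 4–12 synthetic webs (≈ 25 species each), a few hundred
to ~1,000 pairs, and the full ten-topology pool (≈ 10,000 meta-rows); the
acceptance pipeline uses 12 webs.  These sizes were chosen so the entire
suite exercises every stage, including the deep net (scaled to n = 10–20 in
tests), in well under typical CI budgets.  Scaling up is a matter of the
generator's `n_webs`/size parameters; nothing in the pipeline is
size-dependent beyond memory for the mt table.

## Known limitations

* The registry's printed descriptor values cannot be regenerated (unknown
  MI-NODES convention); they are fixtures, and any analysis mixing printed
  and computed descriptors would be inconsistent — the `descriptor_source`
  switch enforces one or the other.
* Published archive-scale accuracies (and the published fitted coefficients)
  depend on the original interaction-web archive and trained weights and are
  not reproduced here; the package instead verifies the arithmetic of the
  published statistics, recovers known discriminants from synthetic data,
  and demonstrates meta-learning lift under controlled conditions.
* Pajek support covers the *Vertices/*Edges/*Arcs dialect with % comments;
  other sections (e.g. *Matrix) are rejected.
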