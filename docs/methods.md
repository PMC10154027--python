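# Methods

## Molecule standardization

A molecule enters any analysis only if it parses, is a single connected
fragment, has more than one heavy atom, contains only H, C, N, O and S, and
has an average molecular weight of at most 500 Da (strict `> 500` is
rejected, so exactly 500 is kept). Rules are checked in that fixed order
and the first failure is recorded, so rejection provenance is reproducible.
"Single atom" is read against the heavy-atom graph because SMILES carry
implicit hydrogens. The "odorous" predicate used to select metabolites is
pluggable and defaults to this filter; no independent volatility model is
re-derived.

## Distance conventions

* **Correlation distance** (embeddings): 1 − Pearson correlation across
  coordinates, computed after each dimension has been centered over the
  *population under analysis* — the union of sampled pair members for the
  correlation stage, all oil compounds for the co-occurrence stage. The
  centering population is part of the metric: sub-population and
  full-population distance matrices legitimately differ.
* **Tanimoto distance** (bit fingerprints): 1 − |A∩B|/|A∪B| over supports;
  two all-zero fingerprints are defined to be at distance 0 so the metric
  is total, though standardized molecules never produce them.
* **L1 / edit distance** (count fingerprints): sum of absolute coordinate
  differences.

Fingerprints are hashed Morgan/circular fingerprints, radius 2, 2048
dimensions by default (configurable); bit fingerprints are the support
indicator of the count fingerprints at equal radius and width.

## Metabolic networks and pair sampling

Each reaction contributes one directed edge from every reactant to every
product; parallel edges from distinct reactions are retained in the edge
set but count once for distances. Metabolic distance is the unweighted
shortest directed path length — the minimum number of reactions converting
one metabolite into another; reversible reactions must be supplied as two
records. Network selection keeps networks with **at least** 100 metabolites
(inclusive threshold, configurable). No currency-metabolite exclusion is
applied by default, but an exclusion list is accepted because hub
metabolites can shortcut paths in real reaction databases.

Because sparse reaction graphs contain far more short-distance pairs than
long-distance ones, the correlation stage samples a fixed number of ordered
odorant pairs (default 50) uniformly without replacement at each exact
distance d = 1..12 with a seeded generator. Ordered pairs (a→b) and (b→a)
are distinct stratum members since the graph is directed. Under-filled
strata keep whatever is available and log the shortfall (strict mode raises
instead), so small networks stay usable.

## Metabolic-distance correlation

Pearson r is computed at the level of individual sampled pairs
(x = discrete metabolic distance, y = continuous representation distance),
not over per-distance bin means; bin-mean correlation is available as an
option. Per-distance means and SDs are returned for dispersion comparisons
between representations, and a multi-seed loop reports the r distribution
under resampling. All sampled pairs are pooled across networks by default
with a per-network breakdown available, since pooling matches the
stratified design.

## Pathway smoothness

Representations of pathway members are compressed by PCA to a common
dimensionality (default 64, capped at the data rank and at n − 1) so that
spaces of different native width are compared without dimensionality bias;
the first two components serve for trajectory plots. For a pathway
A → … → Z, the smoothness of intermediate X is d(A,Z)/(d(A,X)+d(X,Z)) in
the projected Euclidean space. The default "endpoint" mode scores every
intermediate against the pathway's endpoints; a "consecutive" mode scores
triplets of consecutive members instead — both readings of pathway
triplets are defensible, and the endpoint formula is the primary one.
Ratios lie in (0, 1] by the triangle inequality and are invariant under
rigid motions of the representation space (asserted in tests to 1e−9).
Representations are compared by a paired Student t-test over matched
intermediates, two-sided by default with a one-sided option.

## Co-occurrence rank shift

Two molecules co-occur if they share at least one oil. All P = N(N−1)/2
unordered pair distances are ranked ascending with average ranks on ties
(keeping the rank-sum identity exact); a group's rank shift is its mean
rank minus (P+1)/2, the expected rank of a uniformly random pair, with a
normal-approximation 95% CI. The group-weighted shifts of the co-occurring
and non-co-occurring groups cancel exactly, which the test suite asserts
per representation. Between-representation comparisons use paired t-tests
over per-pair rank differences, paired over molecule pairs (not oils),
separately for the two label groups.

## Neural trace processing

Per trial: the trace is smoothed with a centered moving average (window 5;
the window truncates at the trace edges; a trailing window is selectable),
and the trial elicits a response when the smoothed maximum over the 30
frames after odor onset strictly exceeds μ + 3σ of the 30 pre-onset
baseline frames. σ is the population (divide-by-n) SD. By default μ and σ
are established on the **raw** activities: estimating σ from the smoothed
curve deflates it by roughly √window and inflates its sampling variance
(the 30 baseline frames collapse to ~6 effective samples), which makes the
nominal 3σ threshold fire on pure noise roughly 16% of the time for any
stationary Gaussian noise; with the raw baseline the false-positive rate
stays below 1% while a response at SNR 5 is detected essentially always.
The smoothed-baseline variant remains selectable
(`NeuralConfig.baseline_source="smoothed"`). The (odorant, neuron) activity
is the fraction of elicited trials.

Glomerular dF/F matrices are median-subtracted per glomerulus so zero is a
typical baseline; the odor-evoked signal is taken as the negative
deflections of the median-subtracted values, normalized by the glomerulus's
mean squared deviation from zero. Both choices resolve ambiguous
conventions and are isolated in one function, with an RMS denominator
selectable.

## Performance index

Datasets with N ≤ 200 molecules are evaluated leave-one-out, larger ones
fivefold. For each of `n_seeds` seeds (default 5; higher counts reproduce
more expensive protocols) the training data of every split is resampled —
jackknife (delete one point) for LOO, bootstrap (same-size with
replacement) for fivefold — a random forest is fitted, and held-out
predictions are pooled before computing AUROC (rank-based, average-rank
ties) or R² per target. A degenerate classification resample that loses a
class falls back to the un-resampled fold. Indices are averaged over seeds
and targets; the SD across seeds quantifies dispersion, and per-seed
indices support seed-aligned differences between representations. A small
hyperparameter grid (configurable; tree count, class weights, features per
split, minimum samples per split/leaf are the natural axes) is scanned
under the identical protocol and the best entry reported.

Rescaling anchors: 0 = random, 100 = perfect. For classification this is
(AUROC − 0.5)/0.5 × 100 — the anchor definition takes precedence over a
naive ×100 factor, which cannot place perfect AUROC at 100 — and for
regression R² × 100. The neural-distance variant correlates odorant-pair
correlation distances of per-neuron-centered activity with those of
per-feature-centered representations and reports the condition-mean
Pearson r × 100, a choice isolated in one function.

## Synthetic study inputs

The generators reproduce the statistical structure each stage assumes, at
desk scale, as pure functions of a seed:

* **Metabolome** (default 600 metabolites, branching 0.25, 4 fingerprint
  edits per reaction): a directed tree grown from a root, extending the
  most recent node with probability 1 − branching. These defaults yield
  hundreds of available ordered pairs at every metabolic distance 1–12, so
  all sampling strata fill at 50 pairs each. Each product's count
  fingerprint is its parent's with exactly 4 distinct coordinates shifted
  by one, so structural L1 distance grows with metabolic distance with
  mild random-walk cancellation. Pathways are all maximal root-to-leaf
  paths.
* **Embedding** (width 256): a spherical walk — each reaction step rotates
  the parent's unit vector by a fixed angle (0.52 rad) toward a fresh
  direction orthogonal to the whole ancestor path, so ancestor–descendant
  correlation is exactly cos(0.52)^d. The walk is mixed with independent
  Gaussian noise, and the mixing weight is bisected until the pair-level
  Pearson r measured on an internal stratified sample hits the requested
  ρ ∈ [0, 1]; ρ = 0 returns pure noise, and ρ = 1 (or zero noise) returns
  the clean walk, whose recovered r plateaus near 0.96 — the residual gap
  from 1 reflects the mild concavity of 1 − cos^d and population centering,
  not sampling noise.
* **Oils**: metabolic neighborhoods — all metabolites within a graph-ball
  (undirected, default radius 2) of a random anchor; oils with fewer than
  two members are redrawn.
* **Neural traces**: Gaussian baseline noise with a 5-frame ramp to a
  plateau of the planted amplitude for responders (SNR = amplitude /
  noise SD).
* **Evaluation datasets**: targets are a function of the single
  highest-variance feature coordinate (thresholded at the median for
  classification), plus optional noise, or pure noise when uninformative.

What the generators deliberately do **not** emulate: real reaction
chemistry (the fingerprint walk is a statistical stand-in), cycles and
reconvergent pathways (the graph is a tree, so directed pairs are
ancestor–descendant), heavy-tailed oil sizes, correlated neural noise, and
multi-target datasets. Passing tests therefore demonstrate that the
statistics behave as designed under controlled structure — not that the
real-data effect sizes are reproduced; the published real-data correlation
and rank-shift magnitudes depend on MetaCyc, curated oil aggregates and a
trained embedding and are out of scope.

## Numerical choices and degenerate inputs

* Pearson correlations clip to [−1, 1] before forming distances; constant
  vectors raise rather than returning NaN.
* Paired t-tests raise on zero-variance differences (including the
  constant-shift case); AUROC requires both classes; R² requires
  non-constant targets.
* PCA uses the full SVD solver for determinism; effective components =
  min(requested, n − 1, width).
* Representation CSVs are written at 17 significant digits and parsed with
  the round-trip float parser, so save/load is bit-exact.
* All stochastic stages consume `numpy.random.default_rng` generators
  seeded from explicit config fields; identical configs give bitwise
  identical outputs.

## Problem sizes

Default test and demo sizes — 600-metabolite networks, 600 sampled pairs,
oils over ~200 molecules, 100-molecule evaluation datasets with 10 seeds of
leave-one-out — were chosen so every analysis completes in seconds to a few
minutes on one CPU while keeping all sampling strata full and statistical
checks well-powered.
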