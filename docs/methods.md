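# Methods

This note documents the models, conventions and design choices behind
`compfeat`, in enough detail to reproduce or audit any number the
package computes.

## Data model and conventions

Expression data are samples × genes matrices with binary outcome
labels, **1 = poor outcome** (event within five years), **0 = good**.
All sign conventions downstream follow this: t-statistics are positive
when the poor-class mean is higher, classifier scores are
"poor-likeness", and the AUC is the probability that a poor-outcome
sample outscores a good-outcome one.

Every cohort is **z-normalized per gene** to mean 0, sd 1. We use the
sample standard deviation (n−1 denominator) throughout — for
z-normalization, for Welch t-statistics and for the group sds inside
them — since the convention is otherwise unspecified and n−1 is
standard statistical practice. A constant gene column is an error (it
cannot be standardized), reported by gene name. Merging cohorts pools
rows (sample ids prefixed with the cohort name) and re-z-normalizes
the pool. Gene identifiers are opaque strings.

Secondary sources are restricted to genes measured in the expression
data before any search: nodes without expression are dropped from
networks and gene sets, and gene sets that become empty are skipped.
The one exception is hub candidacy (below), which is defined on the
full network.

## Feature extraction

**Activity.** The per-sample aggregate of a gene group S is
`aᵢ = Σ_{j∈S} e_ij / √|S|`. The √|S| normalizer (rather than the plain
mean) keeps the feature variance near 1 on z-scored inputs; since the
two differ by a positive scalar, t-statistics, mutual information and
correlations are identical under either, and the plain mean is
available via `activity(..., norm="mean")`.

**Mutual information.** Activities are discretized into
`⌊log2 k⌋ + 1` equal-width bins spanning the observed range (k =
number of samples); MI is computed in bits between the bin index and
the class label, with 0·log 0 := 0. A constant activity vector
occupies one bin and scores 0. Both the bin-count rule and the
equal-width dissection are our choices where the original description
leaves them open; both are configurable.

**Greedy subnetwork search.** Every measured network node seeds one
greedy run. At each step the candidate gene adjacent to the current
subnetwork and within `max_radius` (default 2) hops of the seed that
maximizes the MI of the subnetwork activity is added; growth stops
when no candidate improves MI by more than `improvement_min` (default
0, i.e. strict increase). Ties in MI gain go to the lexicographically
smallest gene id, which makes the search deterministic and invariant
to node enumeration order. Identical gene sets reached from different
seeds are deduplicated; the final ranking is by MI, descending, with
ties broken on the sorted gene tuple.

**Subnetwork significance filter.** A subnetwork is kept only if its
MI exceeds the (1−α) quantile of three permutation nulls (α = 0.05
default):

1. same-size subnetworks grown from random seeds *with the same greedy
   MI-maximizing rule* as the real search;
2. the size-matched feature population of full searches rerun after
   permuting the gene-to-node assignment;
3. the size-matched feature population of full searches rerun under
   label permutation.

The crucial point in all three is that the null re-applies the
search's own optimization. Comparing optimized observations against
unoptimized nulls (random subnetworks, or the fixed feature under
permutation) is anti-conservative — on pure-noise data several times
α of the features survive, because greedy maximization inflates every
observed MI. With selection-matched nulls the pass fraction on null
data is ≈ α per test, which we verify. Null 1 uses
`n_null_permutations` draws per size (default 1000); nulls 2 and 3 use
`n_search_permutations` full search replicates (default 20 — each
replicate contributes one feature per surviving seed, so the null
population is large even for few replicates).

**CORG pathway search.** Within a gene set, genes are ordered by t —
descending if the gene with the largest |t| has positive t, ascending
otherwise; |t| ties break lexicographically. The prefix of this
ordering is extended while the |t| of the averaged activity strictly
increases, and the final |t| is both the feature score and the
pathway's rank key. Because the search starts at the best single gene,
the score never falls below the best single-gene |t| in the set. All
sets are ranked; collections larger than 400 sets are truncated to the
top 400 by default.

**Hub correlation differences.** Candidate hubs are the top 15% of
nodes by degree in the *full* network (ties at the cutoff included),
before expression filtering — hub status is a property of the
interactome, not of the assay. Hubs without expression data or without
measured interactors are then excluded. For each remaining hub the
average hub difference is the mean, over measured interactors, of
`corr¹(h, n) − corr⁰(h, n)` (class-conditional Pearson correlations;
a class with fewer than three samples is an error; an edge with zero
variance in a class contributes correlation 0 with a logged warning).
Significance is an empirical label-permutation p-value — the fraction
of `n_label_permutations` (default 1000) replicates whose |average
difference| reaches the observed one — at cutoff α = 0.05. Kept hubs
are ranked by |average hub difference|; the absolute value is our
choice, since a sign convention for ranking is not specified. Each
hub feature contributes one classifier dimension per measured
interactor, `e(hub) − e(interactor)`.

## Classifiers

**Nearest mean.** A sample is projected onto the line connecting the
class means; the score is d(projection, good mean) − d(projection,
poor mean). A score of exactly 0 (midpoint) is classified good — an
arbitrary but deterministic tie rule; the AUC is rank-based, so ties
only matter through the half-credit convention. The decision is
invariant under orthogonal transformations of feature space, but not
under column duplication (which changes the metric) — documented, not
asserted.

**Weighted 3-NN.** The three nearest training samples by Euclidean
distance vote with weights `(1/dⱼ)/Σ(1/dₗ)`; a zero-distance neighbor
takes all the weight (split evenly if several are at distance zero).
The weights always sum to 1, so the score is a convex combination of
neighbor labels. The exact weighting formula was an open choice; the
normalized inverse-distance form is implemented behind a single
function so alternatives can be swapped in.

**Logistic regression.** Maximum-likelihood fit with an L2 ridge,
default λ = 1e-4, via scikit-learn's lbfgs solver. The unregularized
mode (`ridge=0`) is retained to reproduce a known pathology: on wide
matrices (more features than samples) the data are linearly separable,
the MLE is at infinity, and no finite optimum exists. Because lbfgs
can stop on its gradient tolerance in this regime, the `converged`
flag is additionally set to False whenever the unregularized fit
perfectly separates its training data. Non-converged classifiers are
flagged on their evaluation records so summaries can exclude them.

**AUC** is computed in the Mann–Whitney form from average ranks, which
implements P(score_poor > score_good) + ½·P(equal) exactly.

## Evaluation protocol

For one (train, test) cohort pair: (1) features are extracted and
ranked on the training cohort; (2) the number of features n* is chosen
by stratified five-fold cross-validation within the training cohort —
features are re-extracted on each fold's 4/5 training part, a
classifier series is trained along the ranking, each series is scored
by AUC on the held-out fifth, and n* is the grid point with the
highest mean AUC (ties to the smallest n); (3) features are
re-extracted on the full training cohort, the final classifier is
trained there, and one AUC is measured on the untouched test cohort.
Fold assignment is seeded from a content hash of the training data
(rows canonically sorted by sample id), so results are reproducible
and independent of input row order. The feature grid defaults to
1..min(#features, 400). For hub features the grid counts feature
*sets* — the edges of a hub are not individually ranked, so a grid
point adds a whole hub.

Fixed-count policies (`fixed_50` etc.) replace step (2); if fewer
features were extracted than requested, the run is recorded as an
explicit infeasibility (AUC = NaN, `feasible=False`), never silently
truncated.

Settings: *paired* produces D(D−1) records for D cohorts; *merged*
produces D (train = the other cohorts pooled and re-normalized);
*ER-stratified* produces D (cohorts are filtered to ER-positive
samples *before* the training pool is merged and re-normalized; a
held-out cohort without usable ER-positive cases yields an
infeasibility record).

Win/loss matrices compare method × source combinations over shared
(train, test) pairs; entry (i, j) is log2((wins+1)/(losses+1)) — the
+1 smoothing keeps all-win entries finite — giving an antisymmetric
matrix with zero diagonal; draws count for neither side. Method
comparisons use the paired Wilcoxon signed-rank test, zero differences
dropped, exact null for small tie-free samples and a
continuity-corrected normal approximation otherwise (scipy's "auto"
rule), with Bonferroni multipliers equal to the family size.

Leakage is auditable: ranked feature lists carry a fingerprint of
(training data, secondary source, parameters), and the acceptance
battery verifies that replacing the test set with noise leaves the
fingerprint, the selected n* and the trained classifier bitwise
unchanged.

## Randomization of secondary data

A randomized instance applies a uniform random bijection over the
source's own gene universe — including unmeasured genes, so the
measured/unmeasured mixture is itself shuffled — to every gene
occurrence. Degree sequences and set-size profiles are exactly
preserved; composing with the inverse permutation restores the source.
The experiment driver reruns the entire evaluation setting per
instance (instances drawn independently) and tests, one-sided and
paired over (train, test) pairs, whether the real source beats each
instance, with Bonferroni correction over instances.

## Signature stability

A signature is the union of member genes of the top-n ranked features
from one cohort. Overlap between two cohorts is measured by the
one-sided Fisher exact (hypergeometric upper-tail) p-value over the
selection universe — all measured genes for single genes, the measured
genes of the secondary source for composite features; a config switch
forces the intersection universe for cross-method comparisons — and by
the Jaccard index with an empirical null of size-matched random set
pairs, p = (1 + #{J_null ≥ J})/(1 + draws). The Fisher p is used as an
overlap *measure* (smaller = more surprising overlap), not as a
hypothesis test. Because a composite signature of n features can
contain many genes, the single-gene control is size-matched per
cohort: the best m single genes, with m the composite signature's gene
count, drawn from the same universe when the common-universe switch is
on.

## Synthetic benchmark

Each cohort draws background expression N(batch offset, 1), with
per-cohort per-gene offsets ~ N(0, `batch_sd`); informative genes gain
a `+effect_size` mean shift in poor-outcome samples; the cohort is
then z-normalized (so the realized class separation is the shift
divided by the inflated total sd, as in real standardized cohorts).
Class labels are drawn to a fixed poor fraction (default 0.28,
matching the 20–35% range of real outcome cohorts); ER status is
Bernoulli(0.7), independent of outcome by default, with a coupling
knob to emulate subtype heterogeneity.

Planted modules are disjoint subsets of the informative genes. Their
members share a per-sample latent factor with loading 0.5; the loading
sign of the non-hub members flips in the poor class (default on).
Without some class-dependent correlation structure the average hub
difference is identically zero in expectation, so a correlation-free
generator could never exercise the hub method; the flip construction
makes hub–interactor correlations +r in one class and −r in the other
while leaving the marginal mean shift untouched.

The network is a configuration-model graph over a power-law-ish degree
sequence (exponent 2.5, minimum degree 1), with 10% of nodes given
identifiers outside the measured gene universe to emulate unmeasured
proteins. Each planted module is wired as a star around its hub gene
plus sparse chain edges (so it is a connected induced subgraph), and
the hub receives a handful of extra random attachments so its degree
falls in the candidate-hub range. Gene sets are drawn uniformly from
the universe, except one planted set per module (the module genes
padded to roughly twice the module size).

What the generator does **not** emulate: platform-specific probe
effects, missing values, correlated background noise beyond the
planted factors, non-Gaussian expression distributions, and survival
censoring. Passing tests therefore demonstrate correctness of the
machinery and qualitative behavior of the methods under a clean
additive-shift model — not performance claims about real tumor
cohorts.

## Validation experiments and problem sizes

The canned experiments (`compfeat.experiments`, also driven by
`scripts/acceptance.py`) use desk-scale versions of the benchmark,
chosen so the full battery runs in a few minutes on one core:

- **Protocol counts**: 6 cohorts × 30 samples × 40 genes; verifies 30
  paired, 5 merged (over five cohorts), 6 ER-stratified records and 15
  stability pairs.
- **Null calibration**: effect 0; 5 cohorts × 60 samples × 80 genes
  for the AUC band (20 pairs); a 60-gene network for the subnetwork
  filter (100 permutations per null) and hub test (200 label
  permutations).
- **Parameter recovery**: 2 cohorts × 100 samples × 150 genes, effect
  2 sd, one 10-gene planted module; measures cross-cohort single-gene
  AUC (CV-optimized over a 1..30 grid), the best Jaccard between the
  top greedy subnetworks and the planted module, and the planted hub's
  permutation p (200 permutations).
- **Leakage guard**: 2 cohorts × 50 samples × 50 genes; reruns the
  pipeline against a noise test set and compares artifacts bitwise.
- **Randomization contrast**: 4 cohorts × 40 samples × 120 genes, 10
  randomized instances, greedy subnetwork features with a fixed count
  of 3, nearest-mean classifier. The *spread* regime (50 informative
  genes, no modules) reproduces the regime in which randomized
  networks still cover enough signal genes to span useful subnetworks
  — essentially no instance is rejected; the *module* regime (8
  informative genes forming one planted module) is the counterfactual
  in which network structure genuinely carries the signal, and the
  real network wins.
- **Stability size correction**: 4 cohorts × 60 samples × 100 genes
  with *no* outcome signal and random gene sets; a sign test across
  cohort pairs checks that the size-matched single-gene control is not
  systematically less stable than the composite signatures. The
  signal-free setting isolates the fairness of the size matching
  itself; with signal present, set-level selection granularity can
  legitimately favor composite stability.

## Known limitations

- The subnetwork search explores a greedy path per seed; the
  acceptance battery only bounds it by the exhaustive optimum on small
  graphs, it does not guarantee near-optimality on large ones.
- The selection-matched significance nulls are calibrated
  per-feature-family; they do not correct for the number of features
  ultimately reported (no FDR across subnetworks).
- Empirical permutation p-values are plain exceedance fractions and
  can be exactly 0 at finite permutation counts; interpret them as
  "below 1/n_permutations".
- The merged and ER-stratified settings re-normalize the pooled
  training cohort but leave the (already z-normalized) test cohort
  untouched; cross-platform location/scale differences beyond additive
  batch offsets are out of scope.
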