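# Methods

`clustagg` selects a single "best" clustering — an (algorithm, number of
clusters) pair — for one numeric dataset by scoring many candidates with
cluster-validation measures and aggregating the per-measure rankings
into a consensus ordering. This note records the models, formulas,
defaults and design choices, and what the synthetic benchmarks do and do
not demonstrate.

## The consensus model

Let the candidate set be the cross-product of requested algorithms and
cluster numbers k. Each validation measure i orders the candidates into
a ranked list V_i with an importance weight w_i > 0 (equal by default;
user weights are rescaled to sum to the number of measures so the
objective's scale does not drift). A proposed ordering L is scored by

    Phi(L) = sum_i w_i * dist(L, V_i)

and the consensus L* minimizes Phi. The head of L* is the reported
best candidate. With a single measure, aggregation is the identity and
the best candidate is simply that measure's top entry.

### Rank distances

For items t with ranks r_L(t), r_V(t) (1 = best) and s_V(p) the
normalized score of V at position p:

* Spearman footrule (unweighted): sum_t |r_L(t) - r_V(t)|.
* Weighted footrule: sum_t |s_V(r_V(t)) - s_V(r_L(t))| * |r_L(t) - r_V(t)|.
  Displacements between near-tied candidates cost little. With equally
  spaced scores this equals (sum of squared displacements)/(kappa - 1);
  note this is *not* a monotone transform of the unweighted footrule
  (permutations with smaller footrule can have a larger squared sum).
* Kendall tau (unweighted): number of discordant pairs.
* Weighted Kendall: each discordant pair (t, u) contributes
  |s_V(r_V(t)) - s_V(r_V(u))|; the score-difference form was chosen over
  a score-sum form and is isolated in one routine for easy replacement.

Scores entering a list are min-max normalized to [0, 1] with the best
candidate at 1; a constant score row normalizes to all ones with a
warning and the list falls back to the deterministic tie rule
(method name lexicographic, then smaller k).

### Optimizers

* **Brute force** (kappa <= 8): enumerate all permutations; ties break to
  the lexicographically first permutation. Serves as the exact oracle in
  tests.
* **Cross-entropy Monte Carlo** (default): a kappa x kappa
  position-probability matrix, initialized uniform, is sampled
  row-by-row without replacement (`sample_size` = 10 kappa^2 permutations
  per iteration), the ceil(rho * sample_size) elite by Phi update the
  matrix by elite frequency blended with factor `smoothing` = 0.7
  (rho = 0.1); stop when the incumbent best is unchanged for 7
  iterations (max 1000). The input lists' own orderings join the first
  batch, so tied optima resolve toward an observed list rather than an
  arbitrary permutation.
* **Genetic algorithm**: population 100 permutations (half seeded from
  the input lists), rank-proportional parent selection, order crossover
  (probability 0.4), per-gene swap mutation (probability 0.01), elitism
  of one, convergence after 30 unimproved generations.

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical seeds give identical results and
traces.

## Clustering engines

Continuous data ("items are rows"): hierarchical agglomerative
clustering ("hierarchical" and its alias "agnes" are one engine; default
linkage is average/UPGMA, with complete, single and ward available),
DIANA (divisive: split the largest-diameter cluster by seeding a
splinter with the object of maximal average dissimilarity and migrating
objects while they are closer on average to the splinter), k-means
(scikit-learn, 10 restarts), PAM (build + swap on the dissimilarity
matrix, first-improvement swaps in fixed index order for
reproducibility; exact on small instances by construction), CLARA (PAM
on 5 random subsamples of size min(N, 40 + 2k), best full-data
assignment kept; degenerates to PAM exactly when the sample covers the
data), FANNY (relational fuzzy c-means on squared dissimilarities,
fuzziness exponent 2; squared dissimilarities make the procedure
coincide with fuzzy c-means in feature space for euclidean input and
give crisp memberships on well-separated data), and a full-covariance
Gaussian mixture (EM, k-means initialization, best of 10 restarts).

The default dissimilarity is euclidean; 1 - Pearson correlation and
manhattan are options shared by clustering and the internal measures.
SOM and SOTA occupy reserved registry slots and raise a clear
not-implemented error. An algorithm that leaves a cluster empty is
treated as a failed candidate, never silently re-run: retries would
break seed determinism.

## Count-data mixtures

Counts (RNA-seq style) are modeled as a k-component mixture with
feature-independent cluster mean profiles mu_cj: Poisson, or negative
binomial with one dispersion phi_c per cluster (variance
mu + phi mu^2; phi -> 0 recovers Poisson; sharing phi across features
keeps the model identifiable at moderate sample sizes). Library-size
normalization is deliberately *outside* the model — it is a
preprocessing option (scale each column to the median column total)
used when feeding counts to the continuous algorithms; the mixtures see
raw counts.

Fitting:

* **EM**: responsibilities r_ic proportional to pi_c f_c(y_i); M-step
  pi_c = mean_i r_ic, mu_cj = responsibility-weighted column mean.
  Dispersions are re-estimated each iteration by responsibility-weighted
  method of moments refined with Newton steps (in log phi, finite-
  difference derivatives, clamped to [1e-8, 1e8]); a candidate phi is
  kept only if it does not lower the weighted profile likelihood, which
  preserves EM's monotone log-likelihood trace. 5 k-means (log1p)
  initializations, best final likelihood kept.
* **Deterministic annealing**: responsibilities tempered as
  (pi_c f_c)^beta with beta rising geometrically from 0.2 by factor 1.2
  to 1 (one EM update per temperature), then plain EM to convergence.
  A single initialization — annealing replaces restarts. beta0 = 1
  reproduces plain EM exactly.
* **Simulated annealing**: classification EM; at temperature T the
  hard assignment is redrawn from responsibilities flattened by 1/T,
  accepted by a Metropolis rule on the classification log-likelihood,
  with proposals that would empty a cluster rejected; T starts at 2.0
  and cools by 0.95 per step to a floor of 1e-3; the best state visited
  is kept and reported as a soft fit.

Convergence: relative log-likelihood change below 1e-6, at most 500
iterations. Rows of all zeros are rejected by name (they admit no
positive mean profile).

## Validation measures

Internal (from the partition and dissimilarities alone):

* Connectivity (minimize): sum over items of 1/j for each of the L
  nearest neighbors (j = 1..L) not co-clustered with the item; L
  defaults to 10 (`neighb_size`); neighbor ties break to the lower item
  index.
* Dunn index (maximize): minimum between-cluster distance over maximum
  within-cluster diameter.
* Silhouette width (maximize): mean of (b_i - a_i)/max(a_i, b_i) with
  a_i the mean within-cluster distance (self excluded) and b_i the
  smallest mean distance to another cluster; singletons score 0.

Stability (leave-one-column-out, all minimized): for every deleted
feature column the remaining data are reclustered with the same
(method, k, seed) — the seed is reused deliberately so the perturbation
measured is the data deletion, not initialization noise. With C(i,0)
and C(i,l) the clusters containing item i in the full and reduced
partitions: APN averages 1 - |C(i,0) ∩ C(i,l)| / |C(i,0)|; AD averages
the full-data distances between all pairs spanning C(i,0) and C(i,l)
(the item-mean reading; a pair-mean weighting across unequal cluster
sizes is the documented alternative); ADM averages the euclidean
distance between the two clusters' full-data mean vectors; FOM is the
root mean within-cluster scatter of the deleted column under the
reduced partition, adjusted by sqrt(N/(N - k)). Count-model candidates
recluster the reduced count matrix with the same mixture fit; AD/ADM
distances always come from the full matrix.

Biological (from a user-supplied annotation; no live ontology access):

* BHI (maximize, in [0,1]): mean over clusters holding at least two
  annotated items of the fraction of ordered annotated pairs sharing a
  class; unannotated items do not count toward cluster sizes.
* BSI (maximize, in [0,1]): mean over deleted columns and classes F
  (|F| >= 2) of |C(i,0) ∩ C(j,l)| / |C(i,0)| over ordered pairs
  i != j in F.

Candidates that fail any measure (degenerate partition, reclustering
failure, undefined measure) are dropped from *all* measures with a
warning, because aggregation requires every list to rank the same set;
fewer than two survivors is an error.

## Synthetic data

The generators provide every input class with known truth and are
bit-reproducible per (parameters, seed):

* Gaussian blobs: cluster means on scaled axis vertices so the nearest
  pair of means sits exactly `separation * sigma` apart, isotropic
  noise sigma.
* Count clusters: a background mean (default 10) with each cluster
  elevating its own block of P/k columns by `fold_change`; negative
  binomial noise via a gamma-Poisson mixture (default dispersion 0.1).
* Annotations: classes aligned to true clusters, each item keeping its
  aligned class with probability `fidelity`.
* Ranked-list ensembles: a planted order perturbed by a set number of
  random adjacent transpositions, equal weights, equally spaced scores.

Benchmark conditions used by the tests and the acceptance script:
mixture recovery uses 2 clusters x 50 items x 10 features at five-fold
change (Poisson algorithms on Poisson draws, negative-binomial
algorithms on gamma-Poisson draws), 20 seeds; end-to-end recovery uses
3 blobs x 20 items x 6 features at 10 sigma separation with
hierarchical/k-means/PAM over k = 2..4 and internal + stability
measures, 20 seeds; optimizer-oracle agreement uses 100 random
instances with 3-6 candidates and 2-5 lists. These sizes keep the full
suite to a few minutes while leaving the conclusions unchanged at
larger n in spot checks.

What passing these benchmarks does *not* show: the generators produce
feature-independent, single-scale signals — no gene-length or GC
effects, no library-size gradients, no zero inflation, no correlated
features, no partial annotations. Performance on real RNA-seq matrices
depends on normalization quality and on how well the validation
measures' assumptions (compact, separated clusters) describe the data.

## Numerical choices and limitations

* Labels are canonicalized to 1..k in order of first appearance; all
  measures are invariant to relabeling (tested under random
  permutations).
* MAP assignment ties break toward the lower cluster index; score ties
  in list construction break by method name, then smaller k; optimizer
  Phi ties resolve toward observed list orders (CE/GA seeding) or the
  lexicographically first permutation (brute force).
* Dispersion estimates at or below zero (under-dispersed clusters)
  clamp to 1e-8 and are flagged, not silently accepted.
* Only full rankings are aggregated (no top-j partial lists); no
  Markov-chain aggregation; no SOM/SOTA; no plotting; no automatic
  choice of measures or weights.
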