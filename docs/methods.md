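# Methods

This note documents the models and procedures implemented in `tspgnn`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Overview

The toolkit implements a two-stage analysis of brain functional
connectomes:

1. **Behavior decoding.** Per subject, functional connectivity (FC) is a
   symmetric N×N Pearson correlation matrix over atlas regions; its upper
   triangle (i<j, row-major) is the edge-feature vector. A penalized linear
   model maps edges to a continuous behavioral score; the edges that
   survive regularization across cross-validation folds define a
   *task-specific subnetwork*.
2. **Disease classification.** The decoded subnetwork restricts the feature
   space — within-subnetwork FC values plus per-node graph-theory measures
   — and subjects are classified transductively by a spectral graph
   convolutional network on a population graph that fuses imaging
   similarity with phenotype agreement.

## Elastic-Net decoding

The decoder minimizes

    sum_i (f(x_i) - y_i)^2 + lambda * sum_j ( alpha |beta_j| + 1/2 (1 - alpha) beta_j^2 )

with an unpenalized intercept; `alpha = 1` is the lasso, `alpha = 0` ridge.
Note the L2 term carries a factor 1/2, so the pure-ridge closed form is
`(X'X + (lambda/2) I)^{-1} X'y` on centered data — the unit tests check
against exactly this form. Fitting is delegated to scikit-learn coordinate
descent after rescaling (sklearn `alpha` = lambda/(2n), `l1_ratio` =
alpha); closed forms and the univariate soft-threshold serve as independent
oracles in the tests, never as the implementation.

Cross-validated decoding is leak-free by construction. Within each of the
k = 10 folds, using training subjects only: edges are screened to the
`top_k` (default 500) largest |Pearson r(edge, score)|, columns are
z-scored, the score is centered, and — when `lambda`/`alpha` are not fixed
— they are selected by an inner 3-fold grid (20 log-spaced lambdas, alpha
in {0.1, 0.5, 0.9}). Held-out subjects are predicted once each;
r / R² / MSE / explained variance / MAE are computed on the concatenated
out-of-fold pairs.

Screening is deliberately univariate against the behavioral score, the
standard connectome-predictive-modeling practice; it is applied inside each
training fold rather than once up front, which costs a little power but
guarantees the held-out estimate is unbiased.

**Aggregation.** The task subnetwork is the set of edges with non-zero
coefficients in at least half the folds (`freq_threshold = 0.5`); the task
node set is the union of their endpoints.

**Permutation test.** Significance of the out-of-fold correlation r is the
add-one-smoothed rank of r among decodes of permuted scores:
p = (1 + #{r_perm >= r_obs}) / (1 + n_perm). Fold assignment is shared
across permutations, and the penalty is frozen at the per-fold median of
the values selected on the observed data, so every permutation fits the
same model family. Re-running the inner hyperparameter search per
permutation would multiply the cost several-hundred-fold without changing
the exchangeability argument materially; the residual asymmetry is checked
empirically by the uniformity calibration below.

A known small-sample property: out-of-fold r under the null has a slight
negative bias (each fold's predictions shrink toward a training mean that
is anti-correlated with the held-out scores), of order -1/n_folds at small
n. The calibration suite tolerates |mean r| up to 0.05 at its study sizes.

## Graph-theory node measures

Sparse graphs are produced by proportional thresholding: negative
correlations are zeroed (the usual connectomics convention — signed values
remain available to the regression/GNN features), then the strongest
`round(d * N(N-1)/2)` edges are kept, ties at the cutoff broken
lexicographically by (i, j). The retained density is chosen on a grid
(default 0.05–0.50, step 0.05) by maximizing cost-efficiency
`E_glob(binary graph) - d`; raw efficiency alone is trivially maximal at
full density, so the wiring-cost penalty is what makes the optimum
informative. Ties prefer the sparser graph.

Eight node measures are computed: strength, clustering coefficient, local
efficiency, PageRank centrality (damping 0.85), betweenness centrality,
eigenvector centrality, flow coefficient, and k-coreness. Weighted
conventions follow the Brain Connectivity Toolbox where the field has a
convention: shortest-path length 1/weight, Onnela clustering with weights
normalized by the graph maximum, Brandes betweenness normalized by
(N-1)(N-2)/2. The flow coefficient (share of a node's neighbor pairs
connected only through it) is defined for binary graphs only. The weighted
k-coreness is the s-core value from strength-threshold pruning — a real
number, unlike the integer binary coreness. The default node-attribute
table is therefore binary + weighted variants of seven measures plus the
binary flow coefficient: 15 columns.

Eigenvector centrality is computed on the largest connected component
(ties by node count, then smallest contained index) and zero elsewhere,
normalized to unit Euclidean norm.

## Classification features and dimension reduction

For a task subnetwork of m nodes, a subject's feature row is the m(m-1)/2
within-subnetwork FC values (optionally only the decoded edges)
concatenated with the m × 15 node-metric values, column names carrying
provenance (`fc:i-j`, `metric:node:name`). Task patterns combine by edge
union; combined patterns are named by sorted task initials (`M_R_S_W`).

Dimension is reduced by recursive feature elimination under a ridge
classifier (regularization 1.0): repeatedly drop the 10% of remaining
features with the smallest |coefficient| (ties drop the higher column
index) until `n_keep` (default 200) remain. Inside classification
cross-validation the RFE — like the z-scoring before it — is refit per
fold on training subjects only.

## Population graph and spectral GCN

Subjects x, y are connected with weight

    W(x, y) = Sim(x, y) * sum_h gamma_h(x, y),

where `Sim = exp(-rho^2 / (2 sigma^2))` with rho the correlation distance
between feature rows, and gamma_h is 1 when phenotype h agrees (continuous:
|difference| < theta, default theta = 2 years for age; categorical — sex,
site: exact match) and 0 otherwise. Entries therefore lie in [0, H], and a
pair disagreeing on every phenotype is disconnected regardless of imaging
similarity. `sigma` defaults to the median correlation distance among
*training* pairs.

The spectral operator is the symmetric normalized Laplacian
`L = I - D^{-1/2} W D^{-1/2}` (isolated subjects keep an identity row), with
spectrum in [0, 2]. Filters are order-K Chebyshev polynomials of the
rescaled Laplacian `2L/lambda_max - I`, evaluated by the T_k recurrence —
no eigendecomposition at train time; the test suite verifies equality with
the spectral-domain evaluation `U g(Lambda) U' X` to 1e-8.

The classifier is a small fully-convolutional network: Chebyshev
convolution layers (default K = 3) with ReLU hidden activations (one
hidden layer of 16 channels, dropout 0.3) and a 2-way softmax output. It
is implemented directly in numpy with hand-derived gradients and Adam
(learning rate 0.005, 200 epochs); at these problem sizes (a few hundred
subjects, thousands of parameters) a framework would add nothing, and the
compact implementation is exactly testable. Training is transductive:
the graph spans all subjects, but the cross-entropy loss is masked to
training subjects, and every fitted statistic upstream (z-scoring, RFE,
sigma) sees training subjects only. Evaluation is stratified 5-fold:
AUC from the softmax class-1 score, accuracy at posterior 0.5.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the physiology of BOLD imaging:

* **Background connectivity** — a shared rank-3 latent-factor loading
  matrix sets baseline edge means (scale 0.35), plus per-subject edge noise
  (sd 0.12). This yields realistic edge-edge correlation without copying
  real data.
* **Validity projection** — assembled matrices are made valid correlation
  matrices by eigenvalue clipping and diagonal renormalization. The
  behavioral signal is computed from the *post-projection* edge values, so
  the planted linear model holds exactly in the emitted data.
* **Behavioral signal** — score = beta × sum of planted-edge values +
  noise, with the noise decorrelated from the signal and scaled so the
  sample R² of the planted predictor equals the target exactly.
  `beta = 0` with no target R² gives a pure-noise null score.
* **Groups and phenotypes** — cases (a configurable fraction, default 1/2)
  get a mean shift `group_delta` on the planted edges before projection;
  ages are uniform on a configured range, sex 0/1 Bernoulli, site a small
  integer. Site effects beyond a label, motion, and hemodynamics are out
  of scope.

Cohorts serialize as `fc/<subject>.tsv` (N×N, header row of node ids),
`phenotypes.tsv`, and `truth.json` recording the planted structure; output
is byte-identical across reruns of the same config, and numeric TSV output
uses 10 significant digits so checksums are stable.

Because the generator is linear-Gaussian with exactly calibrated signal,
passing the recovery and calibration suites shows the estimators are
correct and leak-free under the stated model — it does not show robustness
to the non-Gaussian, motion-contaminated, site-confounded structure of
real fMRI cohorts.

## Validation study sizes

Chosen to make each property measurable with comfortable margins at
routine runtimes:

* Oracle equivalence: 55 random graphs (N ≤ 12 binary, N ≤ 10 weighted),
  plus 20 Laplacian/Chebyshev cases.
* Edge recovery: n = 400 subjects, N = 40 nodes, five planted edges at
  R² = 0.5, 500 screened edges, 500 permutations.
* Null calibration: 200 replicate cohorts (n = 48, N = 10, 6 folds,
  top_k = 15) at 200 permutations each.
* Classifier power/null: n = 200 subjects, 2σ mean shift on 10 of 30
  features, 5 folds; null via label shuffling.
* Leak audit: n = 120, pure-noise features plus a canary column equal to
  the labels on held-out subjects only; a leak-free pipeline must stay at
  chance, while training with all subjects unmasked drives the canary to
  ceiling (the audit's positive control).

## Known limitations

* The permutation test freezes penalties selected on observed data (see
  above); at very small n this leaves a slight mis-calibration that the
  uniformity check bounds empirically.
* Weighted s-core values depend on the strength scale of the thresholded
  graph and are not comparable across densities.
* The GCN is CPU-only by design and sized for population graphs of up to a
  few thousand subjects.
* Partial correlation, tangent-space and dynamic FC, community/rich-club
  measures, and learnable population-graph adjacency are out of scope.
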