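# Methods

## The model

`bridgenet` estimates a Gaussian graphical model (GGM) over symptom scores:
nodes are questionnaire-derived variables, edges are partial correlations
(the association between two nodes after conditioning on all others).
Under multivariate normality a zero partial correlation means conditional
independence, so the sparsity pattern of the precision matrix K is the
network structure, and edge weights are

    rho_ij = -K_ij / sqrt(K_ii * K_jj).

K is estimated by the graphical lasso: penalized maximum likelihood with an
L1 penalty on the off-diagonal entries only,

    max_K  log det K - tr(S K) - lambda * sum_{i != j} |K_ij|,

where S is the marginal correlation matrix of the node scores.  The penalty
level is chosen by minimizing the extended Bayesian information criterion

    EBIC = -2 L + E log n + 4 gamma E log p,

with L = (n/2)(log det K - tr(S K)), E the number of nonzero edge pairs, p
the node count, and gamma the sparsity hyperparameter (default 0.5, the
conventional compromise between sensitivity and specificity).  The penalty
grid is 100 logarithmically spaced values from lambda_max = max |S_ij|
(i != j), the smallest penalty producing an empty graph, down to
0.01 * lambda_max.  EBIC ties are resolved toward the larger penalty
(sparser model).  There is no post-selection refit: reported weights carry
the usual lasso shrinkage, exactly as in the standard EBIC-glasso workflow
this package mirrors.

The default study design is a two-community pediatric comorbidity network:
five anxiety-dimension nodes (A1 separation anxiety, A2 social phobia, A3
panic disorder, A4 physical injury fear, A5 generalized anxiety; each the
sum of its 0-3 coded items, 19 items total) and nine internet-gaming-
disorder nodes (IGD1-IGD9, the DSM-5 criteria, raw 1-5 codes).

## Bridge centrality

Communities are theory-defined, not data-derived.  Bridge expected
influence (BEI) of node i is the signed, unnormalized 1-step sum

    BEI_i = sum_{j : community(j) != community(i)} w_ij.

It satisfies `sum_i BEI_i = 2 * (sum of cross-community edge weights)`,
which the test suite asserts on every fixture.  Bridge nodes are those with
BEI at or above the linear-interpolation empirical 80th percentile of all
node BEIs (both the percentile and the quantile rule are configurable;
selection uses >= so threshold ties are kept).  With 14 nodes and distinct
BEI values this selects exactly 3 nodes.

## Robustness

* **Edge accuracy** — nonparametric bootstrap: resample the n respondents
  with replacement, re-run the entire estimation (correlation, penalty
  path, EBIC selection), and take percentile 2.5%/97.5% bounds per edge
  (percentile rather than BCa, matching common practice in this
  literature).  These intervals describe sampling variability of the
  *regularized* estimator; because lasso estimates are biased toward zero,
  they are not valid coverage intervals for the unshrunk truth — the
  planted-truth experiments below quantify exactly that.
* **BEI stability** — case-dropping bootstrap: at each drop proportion q
  (default grid 0.05 to 0.75 in steps of 0.05), drop floor(q n) distinct
  respondents, re-estimate, and correlate the subsample BEI vector with the
  full-sample one (product-moment by default, rank correlation optional).
  The CS-coefficient is the largest q such that at *every* q' <= q at least
  95% of replicate correlations are >= 0.7.  Requiring the condition at all
  smaller proportions makes the coefficient monotone and immune to spurious
  non-monotone maxima; undefined correlations (constant BEI vectors) are
  excluded with a warning.  By convention CS > 0.5 is read as ideal
  stability and CS > 0.25 as acceptable.
* **Difference tests** — for each pair of edges (or nodes), the percentile
  1-alpha interval of replicate differences; a pair differs iff the
  interval excludes zero.  alpha = 0.05, no multiplicity correction (the
  report carries an explicit note; interpret dense flag matrices
  descriptively).

All bootstrap procedures are bit-reproducible given (data, B, seed); the
pipeline derives per-stage seeds from one master seed via
`numpy.random.SeedSequence` and echoes them in the report.

## Synthetic cohorts

The generator supplies ground truth the field's real datasets cannot: a
planted partial-correlation matrix P*.  Defaults emulate the reference study
design: 23 cross-community edges (20 positive, 3 negative, magnitudes
0.003 to 0.12) with three designated bridge nodes (A2,
A3, IGD5, planted BEI 0.21 each), and within-community edges of 0.15 on a
sparse seeded backbone (a random spanning tree per community plus ~25%
extra edges — the package's own choice of a sparse, connected backbone,
since real within-community structure varies by instrument).
K* = I - P* off-diagonally; if K* were not positive definite the
off-diagonals would be shrunk by a common factor (recorded; construction
fails below 0.5) and the exact implied P* recomputed, so the stored truth
is always self-consistent with K* to 1e-10.

Observed Likert scores are a rounded, clipped location/scale transform of
latent standard normals with correlation matrix derived from (K*)^-1:
`score = clip(round(mu + sigma * z), lo, hi)`.  Per node, (mu, sigma) are
calibrated by least squares on the exact discretized moments (normal-CDF
sums) so the discretized mean and SD match the preset targets — the
defaults are reference values typical of a pediatric anxiety-IGD cohort
(e.g. A1 3.69 (2.43), IGD5 1.33 (0.81)) — as closely as the discrete support allows.  The
calibration is deterministic; the implied cutpoints are exposed as
`TrueNetworkSpec.thresholds`.

What the generator does *not* emulate: item-level measurement error
structure beyond a single-factor approximation (the optional item mode uses
a fixed loading of 0.7), floor/ceiling asymmetries beyond what clipping
induces, response styles, and polychoric-scale associations.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under a known truth, not that real survey data would yield the
same network.

Two systematic effects are worth naming because they bound what recovery
experiments can show.  First, discretization attenuates Pearson
correlations of Likert scores relative to the latent ones (asserted as a
property test); heavily skewed 5-point nodes attenuate most.  Second, the
planted cross-community weights are themselves on the scale of
already-regularized reported estimates; re-estimating them through a
second round of lasso shrinkage biases small edges to zero and large ones
downward.  Consequently percentile bootstrap intervals centred on shrunken
estimates systematically miss the unshrunk planted values of true edges
(while covering true zeros essentially always), and weight-recovery error
carries an irreducible shrinkage component on top of sampling noise — the
reason regularized symptom networks are interpreted through structure and
relative centrality rather than unbiased effect sizes.

## Numerical choices

* Marginal correlations: Pearson on node scores by default, Spearman
  optional; polychoric is out of scope.  Non-positive-definite correlation
  matrices (possible after discretization) are repaired by eigenvalue
  clipping at 1e-8 and renormalisation, with a warning.
* Graphical-lasso solver: `sklearn.covariance.graphical_lasso`
  (coordinate descent), dual-gap tolerance 1e-4, iteration cap 1000 per
  penalty value.  The solver's dual-gap estimate on discretized resamples
  has a numerical floor near 1e-5, so tighter tolerances only burn the
  iteration cap without changing weights at the reported precision;
  terminal gaps within one order of the tolerance are accepted silently,
  larger ones raise a `GlassoConvergenceWarning`.  lambda = 0 is the exact
  unregularized MLE K = S^-1 (checked against direct inversion in tests).
* Edge detection: precision entries with |K_ij| <= 1e-10 are structural
  zeros (the cd solver returns exact zeros; the threshold only guards
  against round-off).
* Degenerate inputs: constant score columns are rejected by name; an
  all-zero correlation matrix degenerates to a single lambda = 0 path with
  a warning; case-drop proportions leaving fewer than p+1 respondents are
  skipped with a warning.
* Layout: Fruchterman-Reingold (networkx `spring_layout`) with |weight| as
  the attraction multiplier — sign is a colour property, not a geometric
  one — rescaled to the unit square; seeded and deterministic, and by
  construction incapable of altering any analysis number.

## Problem sizes used in the shipped experiments

The test-suite experiments run at n = 250-2000 respondents, bootstrap
B = 4-200 and penalty grids of 25-100 values; the pipeline defaults are
B = 1000 and a 100-value grid, matching the conventions of the applied
literature.  These reduced experiment sizes are the package's own choice to
keep the shipped test suite quick while remaining in the regime where the
documented effects (consistency, attenuation, shrinkage) are clearly
visible.

## Known limitations

* Pearson-on-Likert input understates latent associations; a polychoric
  front end would be the natural extension.
* The bootstrap refits share the full-sample penalty *grid policy*, not the
  selected lambda, so replicate networks may change sparsity — intended,
  as it propagates model-selection variability, but it makes edge
  replicate distributions mixtures of zeros and nonzeros.
* BEI percentile selection over 14 nodes is coarse; with ties the bridge
  set can exceed 3 nodes (all-equal BEI selects every node by design).
* The generator's anxiety nodes are simulated at dimension-sum level by
  default; item mode is an approximation meant for exercising the scoring
  layer, not for psychometric realism.
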