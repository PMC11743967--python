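# Methods

## The model

A cohort of participants is described by a feature table `X ∈ [0,1]^{n×p}`
with expert weights `w ∈ R^p_{≥0}`. Dissimilarity between participants is
the weighted Manhattan distance `d(x, y) = Σ_j w_j |x_j − y_j|`; min–max
scaling every column to [0, 1] first keeps the distance from being dominated
by raw scale differences, so the weights alone express relative importance.

Clustering minimizes the within-cluster L1 objective
`Σ_i d(x_i, c_{z_i})` by Lloyd iteration. Because the coordinate-wise
median (not the mean) minimizes `Σ_i |x_ij − c_j|`, centroid updates use the
median; with median updates both the assignment and update steps are
non-increasing in the objective, which the fitted model asserts via its
recorded objective history. The classical mean update is kept behind
`centroid_update="mean"` for comparison but does not descend the L1
objective. Fits take the best of `n_init` seeded restarts (default 10,
random distinct-row initialization, max 300 iterations, convergence =
unchanged assignments). An empty cluster is reseeded at the point currently
worst-fit by its centroid; donors are forced distinct and never drain a
singleton cluster, since two clusters can empty in the same step.

Soft membership is inverse-distance: `m_c(x) = (1/(d_c+ε)) / Σ_{c'}
(1/(d_{c'}+ε))` with `ε = 1e−9`; exact zero distances concentrate the mass
uniformly on the zero-distance clusters, so a point sitting on a centroid
has membership exactly 1 there. The number of clusters is chosen by the
silhouette method computed under the same weighted metric over a grid
(default k ∈ {2..8}); a point in a singleton cluster gets silhouette 0, and
an all-identical input raises rather than returning a meaningless score.
Robustness of the partition to the (subjective) expert weights is reported
as the pairwise adjusted Rand index across fits under different weight
vectors.

## Shapley explanation of membership

The explained quantity is the soft-membership probability `m_c(x)` of one
cluster. A coalition of features takes the participant's values; features
outside the coalition take the column medians of the training table
(the "background participant"). The Shapley value of feature *j* is its
average marginal effect on `m_c` over coalitions, so contributions satisfy
efficiency: they sum to `m_c(x) − m_c(background)`. One-hot indicator
blocks are grouped into a single player (their parent feature): exhaustive
indicators are mutually constrained, and per-feature reporting is what the
summaries need. Exact enumeration (all `2^p` coalitions, vectorized over a
bitmask matrix) is used up to 15 players; beyond that, permutation sampling
estimates the values and reports per-feature Monte-Carlo standard errors,
with the test suite checking agreement with exact enumeration to three SEs.

Cluster summaries average the signed contributions over a cluster's own
members, rank descending, and drop features scoring below a display
threshold (default 0.04); the stacked-bar export mirrors that table.

## Recommendation

For each exercise *e*, let `ū_e` and `σ_e` be the mean and population SD of
its usefulness ratings (0–4) over the whole cohort, and `ū_{c,e}` the mean
among raters with hard label *c* (fitting aggregates by hard assignment;
test-time weighting is soft). The per-cluster score is the normalized
deviation `S_c(e) = (ū_{c,e} − ū_e)/σ_e`, taken as 0 when the exercise is
unrated, has zero dispersion, or the cluster contributed fewer than
`min_cluster_ratings` ratings — i.e. absent evidence, an exercise is assumed
averagely useful, so cold-start exercises remain recommendable. A test
participant's cluster weights are `ω_c = exp(−λ d_c)` with `d_c` the
weighted Manhattan distance to centroid *c*; λ (default 1.0 on the scaled
distance) interpolates between uniform cluster weighting (λ→0) and pure
nearest-cluster recommendation (λ→∞). The expected utility
`U(e) = Σ_c ω_c S_c(e) / Σ_c ω_c` is invariant to rescaling the weights;
exercises are ranked by `U` descending with ties broken by catalogue order,
making rankings deterministic.

## The synthetic cohort

No participant-level data from such trials can be redistributed, so the
generator emulates the study conditions directly and is itself first-class,
tested code. Defaults: 81 participants in four latent profiles of sizes
19/16/24/22; a 30-day trial with two EMA prompts/day answered with
probability 0.8; 17 exercises; life satisfaction on 0–5 with baseline mean
3.06 and endpoint mean 4.1; usefulness on 0–4 with grand mean 3.77; gender
mix 62.1/35.6/2.3% (female/male/no answer).

Two generation regimes coexist:

- **Quota-calibrated attributes.** Gender, country, education,
  socio-economic status and the baseline/endpoint satisfaction scores are
  drawn by largest-remainder quota from their target distributions and then
  permuted across participants. At n = 81 an i.i.d. draw of, say, gender has
  a sampling SD of ≈5 percentage points — larger than the fidelity one wants
  from a cohort emulator — whereas the quota design reproduces the intended
  composition at every seed to within rounding (mean error ≤ 0.5/n).
  Satisfaction scores take a discretized-Gaussian shape (SD 0.95) whose
  integer counts are nudged to pin the sample mean.
- **Profile-driven items.** Each profile shifts its signature 0–5 Likert
  items by a fixed `effect_size` (default 3.0 points from a base level of
  1.5, or down from 3.5 for energetic charge) with i.i.d. Gaussian noise
  (`noise_sd`, default 0.6) and rounding/clipping. The effect size is
  deliberately independent of `noise_sd` so that the noise acts as a pure
  separability dial: at `noise_sd = 0` the profiles are exactly separable
  and downstream clustering recovers them with ARI = 1. Profile 3 carries
  no Likert signature; it is the older-worker profile (occupation and age
  shifted), and profile 2 skews young. The default effect size and noise
  were fixed so that the planted structure behaves like the reference
  conditions: silhouette selection finds k = 4 and hard labels recover the
  planted profiles with ARI ≥ 0.9 across seeds, while leaving visible
  overlap (typical ARI 0.93–0.97, not 1.0).

Usefulness ratings come from a base distribution over {0..4} with mean
exactly 3.77, exponentially tilted ±0.4 per (profile, exercise) so that each
profile likes four exercises and dislikes four — the signal the recommender
is meant to find; the tilts are balanced so the grand mean stays within
±0.02 of the target. Satisfaction check-ins are weekly, linearly
interpolating each participant's baseline to their endpoint score (both
endpoints exact). EMA responses track the satisfaction trajectory on the
0–10 scale with noise, and carry simulated sentiment scores in [0,1] in
place of the NLP text models, which are out of scope. Sessions walk a
two-level decision tree (EMA band at the root, a uniformly answered
follow-up question below) to one of 18 leaves mapped onto the 17-exercise
catalogue.

**What the generator does not emulate:** item–item correlation structure
beyond the profile means, missing data (real-data mode imputes
mode/median with a logged count, but synthetic data is complete),
non-stationary response rates, attrition, and any real relationship between
the text-sentiment scores and the other items. Passing tests therefore
demonstrate that the pipeline recovers structure *of the planted kind*, not
that four clusters exist in any particular real cohort.

## Preprocessing details

The default schema produces exactly 130 post-encoding columns: five
categoricals (17 indicators), age in the study's five bins (16–19, 20–22,
23–25, 26–32, 33+; fixed edges rather than per-sample quantiles so test
participants embed consistently), ten named behavioral items, baseline
well-being, four interaction aggregates (EMA mean and count, usefulness
mean, exercises completed), two text-sentiment means, and 91 filler survey
items. Default expert weights concentrate on the diagnostically meaningful
variables — behavioral items 1.0, occupation and age 2.0 — and nearly
zero-weight the fillers (0.02) and the remaining demographics/aggregates
(0.1), mirroring how domain experts down-weight features they consider
uninformative for profiling.

Numerical conventions: quantile bin edges are inner cut points with
right-closed intervals (a value equal to an edge falls in the lower bin);
duplicate quantiles collapse with a warning, a constant column becomes a
single constant indicator. Indicator columns inherit the parent feature's
weight divided by the block width, so a many-category feature cannot
dominate the distance. Min–max scaling maps a constant column to zeros;
ranges are learned on the training cohort and clipped at transform time.
Zero-weight features are dropped before encoding. Column order is schema
order then category order, fixed, so reruns are byte-identical.

## Problem sizes and numerical tolerances

Test oracles run at deliberately small sizes where brute force is exact:
exhaustive partition search up to n = 10, k = 3; exact Shapley enumeration
up to 8 players; a 6-participant recommender toy checked to 1e−12.
Cohort-scale checks (silhouette selection, profile recovery, top-feature
agreement) use 20 independent seeds of the full 81-participant cohort with
permutation-sampled explanations (32 permutations per participant), which
keeps the whole suite in the low minutes on one core. Membership vectors
are validated to sum to 1 within 1e−9; sampled Shapley values are accepted
within three Monte-Carlo standard errors of exact values.

## Known limitations

- The default expert weights are one plausible elicitation; the package
  reports weight-robustness (pairwise ARI across weight sets) rather than
  claiming the partition is weight-free.
- Exact Shapley mode is limited to 15 grouped players; the 114-player
  default schema always uses sampling.
- The silhouette criterion inherits its known bias toward compact, equally
  sized clusters; the grid search reports the full profile so a user can
  overrule the argmax.
- The recommender is a static post-trial ranker: no online updating of
  utility statistics and no per-session adaptation of the dialogue tree.
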