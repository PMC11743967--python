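# phenorec

Soft behavioral clustering and exercise recommendation for chatbot-based
digital-phenotyping well-being programs.

Digital-phenotyping trials collect a small cohort of participants (tens of
people) but describe each of them with a large number of mixed-type features
— demographics, behavioral self-reports, ecological momentary assessment
(EMA) responses, interaction logs, sentiment scores derived from free text.
With far more features than participants, direct supervised learning of
"which well-being exercise helps whom" is hopeless. `phenorec` implements
the alternative: compress participants into a small number of *soft
behavioral clusters*, explain the clusters, and recommend exercises at the
cluster level.

The package provides, as scikit-learn-style estimators:

- **`phenorec.cohort`** — a seeded synthetic trial generator (81 young
  adults in four planted behavioral profiles of sizes 19/16/24/22, a
  one-month trial with two EMA prompts per day, a 17-exercise catalogue,
  decision-tree chatbot sessions, usefulness and satisfaction feedback),
  standing in for trial data that cannot be redistributed.
- **`phenorec.features.FeatureTableBuilder`** — mixed-type preprocessing
  into a participants × features table: one-hot encoding of categoricals,
  quantile (or fixed-edge) discretization of numerics such as age, per-
  participant aggregation of variable-length event logs, min–max scaling to
  [0, 1], and expert feature weights (zero weight drops a feature). The
  default schema yields 130 post-encoding columns.
- **`phenorec.cluster.SoftL1KMeans`** — K-means under the weighted Manhattan
  distance `d(x, y) = Σ_j w_j |x_j − y_j|`, with component-wise median
  centroid updates (the median, not the mean, descends the L1 objective),
  silhouette-based selection of the number of clusters, and soft membership
  probabilities `m_c ∝ 1/(d_c + ε)` from the centroid distances.
- **`phenorec.explain.ClusterShapExplainer`** — Shapley-value attributions
  of each participant's cluster-membership probability to their features
  (exact coalition enumeration up to 15 grouped players, permutation
  sampling with Monte-Carlo standard errors beyond), plus per-cluster
  summary tables and a stacked-bar contribution chart.
- **`phenorec.recommend.ExerciseRecommender`** — the cluster-weighted
  recommender: per cluster *c* and exercise *e* the normalized utility
  deviation `S_c(e) = (ū_{c,e} − ū_e)/σ_e`; cluster weights from negative
  exponential smoothing of centroid distances, `ω_c = exp(−λ d_c)`; and the
  expected utility `U(e) = Σ_c ω_c S_c(e) / Σ_c ω_c`, ranked descending.

## Worked example

```sh
phenorec run-all --seed 1 --out-dir demo_run
```

prints

```
pipeline complete: k=4, cluster sizes [15, 25, 22, 19], outputs in demo_run
```

The silhouette profile (`demo_run/silhouette.json`) peaks at four clusters
(mean silhouette 0.428 against 0.32–0.41 for the other candidates in
k ∈ {2..8}), matching the four planted behavioral profiles. The cluster
summary (`demo_run/cluster_summary.csv`) ranks each cluster's most
influential features by mean Shapley contribution to the membership
probability of that cluster, e.g.

```
cluster,feature,score,rank
0,energetic_charge,0.05732122953,1
0,social_media,0.05687175109,2
0,online_notifications,0.05260674673,3
```

— cluster 0 here is the "high social-media use, low energy" profile: being
low on energetic charge raises a member's probability of belonging to it by
about 0.057 relative to the background participant. Per-participant
rankings (`demo_run/rankings.csv`) give each participant the full ordered
17-exercise catalogue with expected utilities:

```
participant_id,exercise_id,expected_utility,rank
P001,17,0.2167338268,1
P001,6,0.1608859292,2
```

Expected utilities are in overall-SD units: exercise 17's mean usefulness in
P001's (softly weighted) clusters sits ~0.22 SD above its overall mean.

The same stages are available piecewise (`phenorec generate`, `preprocess`,
`cluster`, `explain`, `recommend`, `validate`) and as library calls; see the
docstrings and `docs/methods.md`.

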