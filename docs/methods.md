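# Methods

This note documents the models, protocols and numerical choices behind
`tinnibench`, in the order the pipeline runs.

## The synthetic cohort model

The generator emulates a retrospective tinnitus case-history database:
a mostly-unlabeled background population with a handful of rare,
expert-diagnosed endotypes embedded in it.

* **Features.** Quantitative questionnaire scores are independent
  Gaussians in native units, clipped to their declared `[min, max]`
  (questionnaire scales are bounded; clipping, not rejection sampling,
  keeps the draw cheap and the tails realistic for scores piling up at
  the ends). Categorical features are independent draws from baseline
  level probabilities.
* **Endotypes.** Membership is mono-label. Counts are deterministic,
  `round(prevalence * n_patients)`, rather than binomial, so fixture
  tests have an exact surface. A quantitative effect entry `D` shifts the
  member mean by `D * sd` — i.e. `D` is the planted pooled Cohen's D —
  and a categorical entry overrides the level probabilities. Members are
  placed at seeded random positions in the table.
* **Labels.** Each endotype labels a seeded `label_fraction` of its
  members; everyone else carries the `"no diagnosis"` sentinel. The
  built-in reference recipe (`make_reference_spec`) labels all members
  of six endotypes with prevalences 8.33%, 1.37%, 1.26%, 0.87%, 0.51%
  and 0.25%, so 12.59% of a 2772-patient cohort is labeled.
* **Missingness** is MCAR: each patient draws a missing rate (constant or
  Uniform(low, high)) and every feature cell is masked independently at
  that rate; the label column is never masked. The reference recipe uses
  Uniform(0, 8/15), calibrated so ~25% of patients exceed the 40%
  patient-filter cut-off and the filter retains ~75% of patients, the
  retention rate reported for the reference clinical cohort. No MAR/MNAR
  mechanism is modelled.
* **What it does not emulate.** Within-patient covariance between
  features (features are independent given the endotype), multi-label
  comorbidity, longitudinal structure, and informative missingness.
  Passing tests therefore show the pipeline recovers *planted,
  independent-feature* structure; they say nothing about correlated
  questionnaire batteries beyond what the imputation test covers (which
  plants correlations explicitly).

The separable recipe (`make_separable_spec`) keeps the six reference
prevalences but gives each endotype signed effects of magnitude 1.5–3 on
six of sixteen generic scales plus one hallmark binary finding; it is the
ground-truth test bed for the end-to-end benchmark, where recovery is
actually decidable.

## Preprocessing

Order is fixed and meaningful: patients are filtered on the full feature
set (missing fraction **strictly greater** than 0.40 removes the
patient), then features on the surviving patients (strictly greater than
0.25), then imputation. Both inequalities are strict by the protocol's
wording ("more than", "higher than"); a fixture in the tests shows
reordering the two filters changes the survivor sets.

Imputation is the MissForest scheme implemented on sklearn forests:
initialise holes with the column mean/mode; sweep features in ascending
missingness order, fitting a random-forest regressor (quantitative) or
classifier (categorical) on the observed rows and overwriting that
feature's holes; stop when the normalised change over imputed cells
(squared change / column variance for quantitative, disagreement rate
for categorical) increases relative to the previous sweep, keeping the
last improving sweep, or after `max_iter = 10` sweeps. Defaults
`n_trees = 100`; the forest seeds are derived per (sweep, feature) from
one `SeedSequence`, so the procedure is deterministic. Predictors are the
current imputed matrix with categorical features as integer level codes
(trees split on codes adequately; one-hot predictors would triple the
width for no measurable gain at these sizes). Observed cells are never
altered.

`encode` (for PCA/t-SNE) z-scores quantitative columns (population sd)
and expands categoricals to **full** one-hot — no reference level is
dropped, so distance methods weight all levels symmetrically. FAMD does
not consume this encoding: it applies its own weighting (below).

## Partitioning

Three independent, endotype-stratified 50-50 partitionings. Within each,
every stratum (each endotype plus the unlabeled group) is shuffled with
the seeded generator and split half/half; per stratum the two sides
differ by at most one patient, and for odd strata the side receiving the
extra patient alternates across partitionings and strata. A stratum of
size 1 goes to the training side with a warning.

The halves are disjoint. The protocol's description mixes resampling
language with equal division; disjoint halves are the reading under
which the four-clustering stability comparison is meaningful (duplicated
samples across halves would leak fit information into the cross
prediction), and the three partitionings are the independent redraws.

## Reductions

* **PCA** on the encoded matrix (full SVD solver — deterministic).
* **FAMD**: z-scored quantitative columns and categorical indicators
  divided by the square root of their observed level proportion, all
  centered, then PCA. On an all-quantitative table this equals PCA on
  the standardized matrix; on an all-categorical table it reproduces
  multiple correspondence analysis up to one global scaling constant
  (both equalities are asserted in the tests, the latter against an
  independently implemented correspondence analysis). A level observed
  zero times carries no information and is skipped; a single-level
  categorical column is degenerate and rejected.
* **t-SNE**: scikit-learn's Barnes–Hut implementation (exact for more
  than 3 components), seeded, **PCA-initialised**. The PCA
  initialisation matters: the stability protocol fits k-means on one
  half's map and predicts the other half's map in raw coordinates, which
  is only meaningful if two maps of samples from the same population
  share orientation and scale. PCA initialisation makes this hold to a
  useful approximation; it remains the protocol's most fragile step, and
  a sign flip of a principal axis between halves would degrade the
  measured stability (this is a property of the protocol, not a bug of
  the implementation). Perplexity must be below the sample count.

Each half of a partitioning is reduced **independently** with identical
hyperparameters and seed — mandatory for t-SNE (no out-of-sample
extension), applied to PCA/FAMD as well for protocol symmetry.

## Clusterers

k-means uses squared Euclidean distance, best inertia over
`n_init = 10` k-means++ starts. Cluster labels are canonicalised to
consecutive integers by descending cluster size (ties by original
label), and prediction assigns the nearest centroid with ties resolved
to the lowest cluster index; re-predicting the training data reproduces
the fit labels exactly. DBSCAN is standard density reachability with the
reserved noise label −1; fitted labels are canonicalised the same way.

## Evaluation criteria

Entropies are natural-log throughout; every reported quantity is a ratio
of entropies and therefore log-base invariant (asserted numerically).

* **AMI** uses max-entropy normalisation and the **exact** expected
  mutual information under the fixed-marginal permutation null, computed
  by the closed-form hypergeometric sum in log-space (`gammaln`). A
  10^5-permutation Monte-Carlo oracle validates it in the tests to
  within 3 standard errors. Degenerate cases return 0: both partitions
  trivial, or |max{H} − E{MI}| below 1e−15. Samples noise-labeled in
  either partition are excluded pairwise.
* **V-measure** (β = 0.1, homogeneity-weighted) is computed **only over
  labeled samples**: in a cohort that is ~87% unlabeled, treating
  "no diagnosis" as a class would reduce the measure to how the
  background splits. The number of evaluated samples is reported
  alongside. Conventions: h = 1 when H(C) = 0, c = 1 when H(K) = 0,
  v = 0 when βh + c = 0. Noise-labeled predictions are excluded.
* **Silhouette** is computed in the clustering (reduced) space — the
  space the clusterer actually saw — with noise excluded and at least
  two clusters required; singleton-cluster samples score 0.
* **Stability**, per partitioning: k-means is fit on each half, both
  models predict both halves, and the two same-half AMIs are averaged
  (an inductive clusterer). DBSCAN cannot predict new samples, so the
  absolute train/test cluster-count difference serves as the
  transductive proxy.

## Benchmark, eligibility and reporting

For each grid point the three criteria are recorded per partitioning and
averaged. The V-measure and silhouette of a grid point are those of the
**training-half fit** (the representative clustering handed to reviewers
is a training-half clustering). Embeddings are computed once per
reduction configuration and half and shared across clusterer
configurations. Grid-point failures are recorded on the record
(`status="error"`) and never abort the sweep; DBSCAN solutions with a
cluster count outside [2, 20] on either half are discarded
(`status="out_of_range"`).

Eligibility: averaged AMI ≥ 0.7 for k-means (with a 1e−12 epsilon so
the inclusive bound survives float averaging) or a count difference of 0
on **every** partitioning for DBSCAN. The shortlist ranks by averaged
V-measure with ties broken by stability, then silhouette, then the
lexicographically smaller hyperparameter tuple; each entry carries the
training-half clustering of its best-V partitioning.

Profiling reports pooled Cohen's D per (cluster, feature), categoricals
expanded to binary level indicators:
D = (mean_in − mean_out) / s_pooled with the usual pooled variance.
Zero pooled variance yields D = 0 when the means agree and a ±∞
sentinel (rendered `">10"`) when a feature separates the cluster
perfectly. The default listing threshold |D| ≥ 0.3 matches the
granularity at which such cluster tables are conventionally reported.
The endotype repartition compares observed per-cluster counts with the
**uniform-over-clusters** null (total/k); a cluster-size-weighted null
is available behind a flag.

## Problem sizes and study conditions in the tests

The acceptance suite runs the end-to-end benchmark on cohorts of 2000
patients (halves of 1000) with the six reference prevalences, planted
|D| ∈ [1.5, 3], and a reduced grid (PCA/t-SNE at 2 components, two
perplexities, k ∈ {4, 6, 8, 10}), taking the median over three seeds;
at these sizes the sweep completes in a few minutes on one core. The
stability checks use 3 Gaussians 12 sd apart (600 samples, k = 3) for
the stable case and 10-dimensional uniform noise (k = 8) for the null:
in low dimensions the k-means tessellation of uniform data is itself
geometrically reproducible (2-D uniform noise scores ~0.7), so the
10-D setting is the regime in which "noise has no stable structure"
actually holds.

## Known limitations

* Cross-half prediction on t-SNE maps relies on PCA-initialised
  orientation agreement; there is no alignment (e.g. Procrustes) step.
* The MissForest stopping statistic mixes scaled quantitative change
  with categorical disagreement as a plain sum, following the original
  scheme; with wildly unbalanced column counts the two terms can
  dominate one another.
* DBSCAN's count-difference proxy is a weak stability notion: two
  clusterings with equal counts can still disagree arbitrarily.
* The exact E{MI} sum is O(|U||V| · min(a_i, b_j)) per table; fine up to
  a few thousand samples and tens of clusters, not for very large k.
* Silhouette under t-SNE inherits the usual caveat that distances in a
  t-SNE map are not calibrated; it is reported, not used for selection.
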