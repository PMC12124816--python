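# Methods

`twinmap` implements a prognostic and treatment-guidance workflow for women
aged 70+ with HER2-negative early breast cancer: patients are re-expressed as
standardized deviations from a favorable-outcome reference population
("digital twins"), embedded into a 3D manifold, stratified into prognostic
clusters by kernel density modes, and — for an individual query patient —
compared against their nearest treated and untreated manifold neighbors to
read off an expected chemotherapy benefit, together with a statistical check
that such a comparison is admissible.

## Cohort model

A patient record carries nine pre-treatment predictors — age (years), tumor
size (mm), SBR grade binarized (low 1–2 = 0, high 3 = 1), number of involved
lymph nodes, hormone-receptor status (positive iff ER or PR staining ≥ 10% of
tumor cells; the cohort is HER2-negative, so HR-negative means triple
negative), hemoglobin (g/dL), lymphocyte count (G/L), BMI (kg/m²) and
presence of any comorbidity — plus treatment flags and outcome fields.
Treatment variables are deliberately excluded from the predictor vector: the
representation must describe the patient *before* a treatment decision.

The outcome is overall survival at five years (60.0 months; a death at
exactly 60 months counts as a 5-year death — the boundary convention is
closed and unambiguous).  Eligibility requires a resolvable outcome: at
least 60 months of follow-up, or death (which resolves the outcome at any
follow-up length).  Records missing any predictor source field are dropped
(complete-case analysis; no imputation, matching the source protocol of the
cohort this workflow is designed for).

## Digital-twin deviation scoring

The reference class is the set of patients alive at five years and
relapse-free at last follow-up.  A seeded random half of them calibrates the
scorer; all remaining patients (the unselected half plus every
non-reference patient) form the model data, keeping calibration and modelled
populations disjoint.

Calibration learns a robust per-predictor center (median) and scale
(IQR/1.349) on the reference predictors.  Where the IQR is zero without the
predictor being constant — routine for skewed binary predictors such as
HR status at ~80% prevalence — the scale falls back to the sample standard
deviation, and only a truly constant predictor receives the 10⁻⁶ floor.
Without the fallback the floored axis dominates the metric by six orders of
magnitude and destroys the geometry.  Robust standardization makes the whole
representation equivariant under affine rescaling of any raw predictor
(units of measurement cannot matter), which is property-tested.

A patient's deviation vector is their standardized predictor vector minus
the componentwise mean of their digital-twin neighborhood in the
standardized reference.  By default the neighborhood is the *entire*
reference group, so the deviation measures the patient's offset from the
favorable-outcome population norm.  A finite `k_twins` (nearest reference
rows, Euclidean metric, distance ties broken by reference row order for
determinism) gives a local contrast instead — "how do I differ from the
favorable patients most similar to me?" — which is useful for inspecting an
individual but deliberately *not* the default: a fully local neighborhood
mean-centers every patient within their own profile group, which erases
exactly the between-profile structure the downstream stratification exists
to find.  Binary predictors enter the distance as standardized 0/1 values;
no bespoke mixed-type metric is used.

## Manifold stratification

Deviation vectors are embedded into 3D with UMAP.  The embedding
neighborhood is large by default (`n_neighbors=120`, capped at n−1): with
three binary predictors, each archetype fractures into discrete sub-cells
(one per binary combination), and a small, local neighborhood embeds those
sub-cells as separate blobs, over-separating the population; a neighborhood
of the order of an archetype's size keeps each archetype connected while
preserving between-archetype separation.  `min_dist` stays at 0.1; the seed
is explicit and fixed.

Clusters are mean-shift modes of the embedded cloud.  The kernel bandwidth
defaults to the pairwise-distance quantile rule (quantile 0.15 on a
subsample of ≤ 1000 points).  Quantile 0.15 rather than a larger value
because with ~6 comparable clusters only ~1/6 of point pairs are
within-cluster; a quantile above that fraction measures between-cluster
distances and bridges adjacent blobs.  Two guards handle degenerate
geometry: identical coordinates yield a single cluster rather than a crash,
and a partition whose silhouette on the embedding falls below 0.4 is
collapsed to one cluster — mean-shift finds several spurious modes on any
homogeneous cloud, and measured silhouettes separate cleanly (≈ 0.25 for
spurious partitions of an embedded single Gaussian vs ≥ 0.89 for genuine
archetype partitions).  Both the bandwidth and the silhouette guard are
config-overridable (`bandwidth=...`, `structure_silhouette_min=0`).

Clusters are relabelled by decreasing size.  Clusters with fewer than 10
members are reported but flagged *minor* and excluded from prognosis
labelling, since their mortality estimate is too unstable.  Major clusters
are labelled **good** when observed 5-year survival exceeds 80%, **poor**
when 5-year mortality reaches 35%, **intermediate** otherwise; the
good/poor thresholds are the published prognostic conventions, the
intermediate band an implementation convention.  Note that when the
summary is computed on model data, mortality is inflated relative to the
whole population, because half of the good-outcome patients were removed
into the reference group; labels should be read with that denominator in
mind.

Out-of-sample projection maps a new deviation vector to 3D by
inverse-distance-squared interpolation over its 3 nearest training
deviations; an exact match of a training row reproduces that row's
embedded coordinate, duplicates project identically, and the map is
deterministic.  The embedder's own transform was evaluated and rejected: it
places training rows visibly off their own coordinates and shifts held-out
points systematically, which the stability protocol (below) correctly
flags.  Three neighbors rather than five keeps the interpolation's inward
shrinkage below what the stability test can detect at cohort scale.  A
pleasant side effect: a fitted manifold serializes entirely to JSON
(training deviations, coordinates, labels, bandwidth) with no opaque
embedder state.

## Chemotherapy-benefit estimation

A query patient is projected onto the manifold; the 15 nearest
chemotherapy-treated and the 15 nearest untreated patients (Euclidean in
3D, arms selected independently, ties broken by row index) form the
comparison groups.  Kaplan-Meier curves per arm (lifelines' product-limit
estimator; follow-up truncated at 120 months for display) and a two-group
log-rank test summarize the apparent benefit.

The comparison is only meaningful if the two arms occupy the same region of
the manifold.  Comparability is quantified by the symmetrized
Kullback-Leibler divergence D(P‖Q) + D(Q‖P) between the arms' Gaussian
kernel density estimates (Scott's rule, per group), each directed term
Monte-Carlo-averaged over that group's own sample points with densities
floored at 10⁻¹².  The own-group density uses a leave-one-out correction —
a KDE evaluated at its own sample points includes each point's own kernel,
which biases the plug-in estimate upward by ~25–30% on the offset-Gaussian
oracle — and the sum is truncated at zero, since a divergence is
non-negative by definition.  With the correction, the estimate on two unit
3D Gaussians offset by δ=1 matches the closed form δ² (0.95–1.16 over
seeds at n = 2000).

Significance comes from a permutation test: the pooled arms are re-split B
times (default 1000) preserving group sizes, and p is the proportion of
permuted divergences at least as large as the observed one.  This literal
count/B formula admits p = 0; `plus_one=True` switches to the standard
(count+1)/(B+1) estimator.  Arms are declared comparable when p > 0.05.
The test's empirical type-I error is 0.055 over 200 null replicates at
B = 200 (binomial band 0.05 ± 0.031).  When the arms are not comparable the
report's verdict carries an explicit heterogeneity warning — at a realistic
12% treatment rate this is the common case, because the 15 nearest treated
patients are necessarily far more dispersed than the 15 nearest untreated;
the KM contrast is then confounded by profile differences and must be read
with caution.

## Validation protocols

**Stability.** The clustered model data are split 70/30 within each cluster
(training fraction rounded up per cluster; singleton clusters go to
training with a warning), the embedding is refitted on the training part
alone, held-out points are projected onto the fresh manifold, and each
original cluster's training vs projected points are compared with the
symmetric-KL permutation test.  Over 10 initializations (splits + embedder
seeds), the manifold is declared stable when every cluster's median p
exceeds 0.05.  On the default synthetic cohort (n = 2000) the protocol
passes with wide margins (all medians ≥ 0.14).  It is deliberately strict:
on *featureless* Gaussian blobs — clusters whose internal geometry is pure
noise — the test flags the projection's smoothing at any moderate
per-cluster size, for every projection mechanism evaluated.  Passing
therefore requires clusters with genuine internal structure, which the
synthetic cohort (and any real cohort) has.

**Predictive power.** Stratified 5-fold cross-validation of a random forest
(200 trees) and an RBF support-vector classifier (after standardization) on
the 9 predictors against 5-year mortality; the SVC contributes decision
scores, not hard labels, to the ROC.  Mean and SD of AUC and accuracy are
reported per classifier, plus the forest's impurity-based importance
percentages (summing to 100) from a refit on all data.  Sanity limits are
tested rather than external values: AUC ≈ 1 on a separable synthetic
outcome, ≈ 0.5 on permuted labels.

## Synthetic cohort generator

The generator is the package's test bed and emulates the population the
workflow targets: a six-component mixture of patient archetypes.  Per
archetype it fixes the nine feature means (e.g. the large-tumor archetype:
tumor size 65.8 mm, 6.2 involved nodes; the anemic archetype: hemoglobin
11.9 g/dL), a 5-year mortality (0.12 for the three good-prognosis
archetypes, 0.25 and 0.30 for two intermediate ones, 0.40 for the poor
one — chosen once inside the published prognostic bounds of >80% survival
and ≥35% mortality), and an equal mixing weight (cluster sizes are not
published).  Continuous features are truncated normals (age at 70, the
rest at 0; node counts rounded to integers) with spread equal to 15% of
the feature's cross-cluster mean range (floored at 0.5 for counts) —
dispersions are not published, and this value keeps archetypes
distinguishable without being trivially separated.  Binary features are
Bernoulli with the archetype prevalence.  ER/PR percentages are generated
consistently with the positivity flags (threshold 10%; PR positive with
probability 0.85 given ER positive), and SBR grade is 3 for high-grade
draws, else 2 with probability 0.77.

Survival is exponential within archetype with monthly rate
λ = −ln(1 − mortality₅y)/60, so the 5-year death probability equals the
archetype's mortality exactly; chemotherapy multiplies λ by a configurable
hazard ratio (default 1.0 — no fabricated benefit; scalar or per-cluster).
Treatment is Bernoulli at rate 0.12 (the published treatment prevalence),
optionally biased toward high-mortality archetypes by a log-odds shift to
emulate confounding by indication.  Deaths after 60 months are recorded as
5-year survivors; survivors' follow-up is uniform on [60, 120] months (so
every generated record is eligible), and survivors relapse with probability
0.05 — a design constant exercising the reference class's relapse
exclusion.  Everything is driven by one integer seed; identical configs
give byte-identical cohorts.

What the generator does *not* emulate: missing data (real cohorts lose a
third of records to the complete-case filter; generated ones lose none),
correlations between features within an archetype, the joint TNM staging
distribution, non-exponential hazards, and cause-specific mortality.
Passing tests on this cohort therefore demonstrates that the machinery
recovers structure that is present and calibrated as stated — not that the
nine predictors suffice for any particular real population.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `k_twins` | `None` (whole reference) | twin neighborhood size; integers give local contrast |
| `reference_fraction` | 0.5 | share of reference-eligible patients used for calibration |
| `n_components` | 3 | embedding dimension |
| `n_neighbors` / `min_dist` | 120 / 0.1 | embedder locality (see rationale above) |
| `bandwidth_quantile` | 0.15 | mean-shift bandwidth rule |
| `structure_silhouette_min` | 0.4 | spurious-partition guard |
| `min_cluster_size` | 10 | below this a cluster is minor, unlabelled |
| `projection_neighbors` | 3 | out-of-sample interpolation neighbors |
| `k` (benefit) | 15 | neighbors per treatment arm |
| `n_permutations` | 1000 | permutation count (200 in the validation protocols) |
| comparability threshold | 0.05 | p above this ⇒ arms comparable |
| good / poor thresholds | 0.80 survival / 0.35 mortality | prognosis labels |

## Known limitations

- The nearest-neighbor benefit comparison carries no causal adjustment (no
  propensity scores or matching weights); the KL comparability check guards
  against gross spatial confounding on the manifold, not against
  unmeasured confounders.
- Prognosis labels computed on model data use a mortality denominator
  depleted of good-outcome patients (half were consumed by calibration).
- The stability protocol is over-sensitive on clusters with noise-only
  internal geometry (see above).
- Grouped-median age assumes the open ">90" bin spans 90–94.
- The generator's archetypes are axis-aligned and uncorrelated within
  cluster; real patient heterogeneity is richer.
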