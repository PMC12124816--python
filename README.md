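# twinmap

Prognostic stratification and individual chemotherapy-benefit estimation
for **older women (70+) with HER2-negative early breast cancer** — a
population underrepresented in trials, for whom adjuvant-therapy decisions
are routinely made with tools trained on younger cohorts.

The package is aimed at biostatisticians and clinical data scientists who
have a patient-level table with nine pre-treatment predictors (age, tumor
size, SBR grade, nodal involvement, hormone-receptor status, hemoglobin,
lymphocytes, BMI, comorbidity), treatment flags and 5-year follow-up, and
who want cluster-level prognosis and per-patient treatment-benefit
readouts rather than a single risk score.

## Method

1. **Digital-twin scoring.** Patients alive and relapse-free at 5 years
   form a reference population; a random half calibrates a robust
   standardization (median / IQR·1.349⁻¹ per predictor). Every modelled
   patient *x* becomes a deviation vector
   **d** = z(x) − mean(z(twins)), where the twins are the patient's
   digital-twin neighborhood in the standardized reference (the whole
   reference by default, the k nearest rows if `k_twins` is set).
2. **Manifold stratification.** The deviations are embedded in 3D (UMAP)
   and stratified with mean-shift; each cluster is summarized by its raw
   predictor means and observed 5-year mortality, and labelled *good*
   (S(60 mo) > 0.80), *poor* (mortality ≥ 0.35) or *intermediate*.
3. **Benefit estimation.** A query patient is projected onto the manifold;
   its 15 nearest chemotherapy-treated and 15 nearest untreated patients
   yield two Kaplan-Meier curves S(t) and a log-rank test. Arm
   comparability is verified with the symmetrized Kullback-Leibler
   divergence D(P‖Q)+D(Q‖P) between the arms' 3D kernel densities,
   calibrated by a permutation test (p = #{KL★ ≥ KL}/B); when the arms are
   not comparable the verdict carries an explicit heterogeneity warning.
4. **Validation.** A 70/30 per-cluster refit-and-project protocol over 10
   embedder initializations checks manifold stability (all per-cluster
   median permutation p > .05), and stratified 5-fold RFC/SVC
   cross-validation quantifies the predictive power of the nine predictors
   for 5-year mortality.

A seeded synthetic-cohort generator (six patient archetypes with fixed
profile means, exponential within-cluster survival pinned to each
archetype's 5-year mortality, 12% chemotherapy rate, configurable
treatment effect) provides the test bed for every stage. Full details and
parameter rationale: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a cohort, fit the model, and assess chemotherapy benefit for one
high-risk patient. Here the cohort is generated with a 50% treatment rate
and a protective effect (hazard ratio 0.4) confined to the poor-prognosis
archetype:

```bash
cat > gen.yaml <<EOF
chemo_rate: 0.5
chemo_hazard_ratio: [1.0, 1.0, 1.0, 0.4, 1.0, 1.0]
EOF
twinmap simulate --n 1000 --seed 7 --config gen.yaml -o cohort.csv
twinmap fit cohort.csv --seed 7 --outdir model
# query.csv holds one large-tumor, node-positive patient row
twinmap benefit model query.csv --k 15 --permutations 500 --seed 1 --outdir out
```

which prints

```
log-rank chi2=6.600, p=0.0102 (15 chemotherapy vs 15 untreated nearest neighbors)
arm comparability: symmetric KL=1.934, permutation p=0.2080 -> comparable
```

Reading: among the 30 manifold neighbors of this patient the treated arm
survives significantly longer (log-rank p ≈ 0.01), and the two arms occupy
the same manifold region (permutation p = 0.21 > 0.05), so the comparison
is admissible — this profile is predicted to benefit from chemotherapy.
At a realistic 12% treatment rate the same command typically reports
`NOT comparable` with a heterogeneity warning instead: the nearest treated
patients are then spread over a much wider region than the nearest
untreated ones, and the survival contrast must not be read at face value.

`twinmap fit` also writes `cluster_summaries.json`; on the default
six-archetype cohort (n=1000, seed 7) the recovered clusters include

```
cluster 0: n=119 size=65.6mm hb=13.0  mort=0.61  poor     <- large-tumor archetype
cluster 3: n=102 size=31.2mm hb=11.9  mort=0.41  poor     <- anemic archetype
cluster 5: n=100 size=20.2mm hb=13.3  mort=0.16  good
```

i.e. the generator's large-tumor (65.8 mm) and low-hemoglobin (11.9 g/dL)
archetypes are recovered at their profile means. (Mortality here is
computed on model data, which excludes the calibration half of the
good-outcome patients, so it reads higher than the population rate.)

Everything is also available as a library:

```python
from twinmap import run_synthetic_stratification

res = run_synthetic_stratification(n=2000, seed=0)
res.manifold.n_major_clusters_       # 6
res.major_summaries[0].feature_means # raw-scale cluster profile
```

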