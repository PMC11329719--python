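# pdsubtypes

Atrophy-based subtyping of Parkinson's disease (PD) from multi-cohort
structural MRI morphometry.

PD is clinically heterogeneous, and data-driven clustering of brain atrophy
measures is a standard route to biological subtypes — but the result depends
critically on whether the clustering input is adjusted for *global* atrophy.
Without that adjustment, clusters tend to order patients along a single
**severity** gradient (overall neurodegeneration); with it, clustering
instead surfaces **typicality** — distinct regional atrophy *patterns* at
comparable overall burden.  `pdsubtypes` implements both analyses head to
head on pooled multi-cohort data, for neuroimaging researchers who want a
tested, reproducible reference implementation of this pipeline (and a
synthetic multi-cohort generator to exercise it without any data access).

## The method

Input is a subjects × 41 matrix **X** of hemisphere-averaged FreeSurfer-style
morphometry: 34 Desikan-Killiany cortical thicknesses (mm) and 7 subcortical
gray-matter volumes (mm³), plus eTIV, WM-hypointensity volume and clinical
covariates.

1. **Harmonization** (residual method, reference-group fits): for feature
   *j* and covariate *c*, `x_ij ← x_ij − β_j (c_i − c̄_ref)` with β_j fit by
   OLS on the reference group (healthy controls for field strength and eTIV;
   all subjects, largest cohort as reference level, for cohort offsets).
   Applied in order: field strength → eTIV (volumes) → cohort.
2. **Severity normalization** (adjusted mode only): thickness values are
   divided by the subject's mean cortical thickness, volumes by the
   subject's total (eTIV-adjusted) subcortical GM volume — after which every
   subject's mean thickness ratio is exactly 1 and only the regional pattern
   remains.
3. **Unsupervised random forest**: a synthetic contrast class is drawn from
   the product of the feature marginals; a forest learns real vs synthetic;
   proximity `p_ij` = fraction of trees where subjects *i, j* share a leaf.
4. **Classical MDS** on `d_ij = √(1 − p_ij)` (Torgerson double-centering,
   eigendecomposition), keeping 3 components (scree-validated).
5. **Average-linkage (UPGMA) hierarchical clustering** of the embedding;
   the number of clusters is chosen by **majority vote of 13 internal
   validity indices** (Calinski–Harabasz, Dunn, silhouette, Davies–Bouldin,
   C-index, McClain–Rao, point-biserial, Gamma, Xie–Beni, Ball–Hall,
   Hartigan, Ratkowsky–Lance, trace-W), ties toward smaller k; clusters with
   < 10 members are excluded from characterization.
6. **Characterization**: Kruskal–Wallis / Pearson χ² cluster comparisons
   with Dunn/Holm post-hocs; per-ROI ANCOVA vs controls with
   Benjamini–Hochberg FDR and pooled-SD Cohen's *d* (positive = more
   atrophy); cross-solution transition tables (χ², adjusted Rand index);
   and linear mixed models `score ~ time × cluster × age + (1 | subject)`
   for 6-year UPDRS-III / MoCA trajectories with Tukey slope contrasts.

## Worked example

```python
from pdsubtypes import simulate, AtrophySubtypeModel
from sklearn.metrics import adjusted_rand_score

cohorts = simulate.default_cohorts(scale=300/633)   # 4 cohorts, ~300 PD
subtypes = simulate.severity_subtypes()             # planted severity gradient
table, matrix, truth = simulate.generate_dataset(cohorts, subtypes, seed=1)

res = AtrophySubtypeModel(table, matrix, mode="unadjusted", n_trees=500).fit(seed=1)
print(res.summary())
```

```
Atrophy subtyping results
=========================
mode: unadjusted   seed: 1   config: a3173fca7c43
PD subjects clustered: 300   HC reference: 111
adjustment chain: residual:field_strength -> residual:etiv -> residual:cohort
ensemble vote: winner k=3, runner-up k=15
vote tally: {2: 1, 3: 4, 4: 2, 6: 1, 14: 2, 15: 3}
retained clusters (3, min size 10): cl1=118, cl2=110, cl3=72
MDS: 3 components, top eigenvalue share 0.28
```

The vote lands on k=3 and the labels recover the planted subtypes with
adjusted Rand index 0.915.  Characterization shows the expected severity
profile — clusters differ in age (H=16.8, p=2e-4), UPDRS-III (H=47.3),
MoCA (H=83.6) and WM-hypo/eTIV (H=110.3), but not in disease duration
(p=0.51).  Longitudinal mixed models recover the planted motor decline:

```python
visits = simulate.generate_longitudinal(table, subtypes, seed=1)
print(res.fit_trajectories(visits, outcome="updrs3").summary())
```

```
time x cluster omnibus: chi2=162.743 (df=4), p=0.0000
per-cluster slopes (points/year at mean age):
  cluster 1: +0.971 (se 0.080)
  cluster 2: +1.706 (se 0.082)
  cluster 3: +2.480 (se 0.093)
Tukey-significant slope contrasts: 1 vs 2, 1 vs 3, 2 vs 3
```

(planted slopes: 1.0, 1.8, 2.5 points/year).  Running the same data with
`mode="adjusted"` removes the severity axis — between-subtype differences in
mean thickness become exactly zero — which is how pattern (typicality)
subtypes are isolated.

A CLI wraps the same objects: `subtype simulate`, `subtype run`,
`subtype compare` (see `--help`).

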