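# Methods

## Data model

The unit of analysis is a subject with 41 hemisphere-averaged morphometry
features: 34 Desikan-Killiany cortical thicknesses (mm) and 7 subcortical
gray-matter volumes (mm³: thalamus, caudate, putamen, pallidum,
hippocampus, amygdala, accumbens), plus eTIV (mm³), white-matter
hypointensity volume (mm³), and clinical covariates.  Wide input tables use
`lh_`/`rh_` FreeSurfer-style column prefixes; hemispheres are averaged
arithmetically on ingestion.  Missing clinical values are retained and
handled by per-variable pairwise deletion, so per-variable Ns may differ.

## Harmonization chain

Scanner, head-size and site effects are removed with the residual method:
coefficients estimated in a designated reference group, the fitted effect
subtracted from everyone.

* **Continuous covariates** (eTIV): per-feature OLS on the reference group;
  adjusted value = `x − β (c − c̄_ref)`.  Subtracting the *deviation* from
  the reference mean (rather than the full prediction) preserves the
  feature's level.  This matters because the severity step below divides by
  per-subject totals, which must stay positive; it changes nothing for
  clustering, which is translation-invariant per feature.
* **Categorical covariates** (field strength, cohort): per-level mean
  offsets relative to a reference level; reference-level subjects are
  untouched.
* **Order**: field strength → eTIV (volume features and WM-hypo) → cohort.
  Field-strength offsets are estimated on healthy controls, but only within
  cohorts whose controls span both field strengths: in a pooled sample
  where scanner mix differs by site, a cross-site contrast would confound
  the scanner offset with site offsets (we verified that the pooled
  estimator leaks site offsets of the same order as the scanner offset
  itself).  Cohort offsets are estimated from all subjects (PD + HC)
  because one cohort has no controls; the largest cohort is the reference
  level.  eTIV fits use pooled HC.
* **WM-hypo** is eTIV-residualized inside the chain but reported as the
  plain WM-hypo/eTIV ratio in characterization tables.

## Severity (global atrophy) normalization

"Adjusted at the individual level" is implemented as per-subject division:
each thickness by the subject's mean over the 34 cortical ROIs, each volume
by the subject's total (eTIV-adjusted) subcortical GM volume.  Consequences
used as test invariants: every subject's mean thickness ratio is exactly 1;
the output is invariant to any per-subject global rescaling of the input;
any planted between-group difference in mean thickness is exactly zero
after adjustment.  A residual-on-normalizer alternative was considered and
rejected as the default because the division form makes the removal of the
severity dimension exact rather than approximate.

## Clustering engine

* **Synthetic contrast class**: each feature resampled independently with
  replacement from its own marginal (product-of-marginals null), preserving
  univariate distributions while destroying dependence.  An all-constant
  feature matrix is rejected (no contrast to learn).
* **Forest**: scikit-learn `RandomForestClassifier`, default 2000 trees
  (500 in the reduced verification experiments; proximity standard error
  scales as 1/√trees).  `min_samples_leaf` defaults to n/12 (min 5): with
  singleton leaves, co-leaf proximity saturates at zero for all but nearest
  neighbours and the MDS embedding degrades toward a chain, which we found
  cuts planted-gradient recovery (ARI) by ~0.1-0.3; leaves of ~n/12 keep
  proximities informative at cluster-scale distances.
* **Proximity → dissimilarity**: `d = √(1 − p)` (closer to Euclidean
  behaviour for RF proximities; plain `1 − p` available by config).
* **Classical MDS** (Torgerson): double-center `−D²/2`, eigendecompose,
  scale eigenvectors by √eigenvalue (negatives clipped, short spectra
  zero-padded with a warning).  Exact for Euclidean inputs (tested to
  1e-8).  The production dimension is fixed at 3; a scree rule (largest
  drop in successive eigenvalue ratios) is available for data-driven
  choice.
* **Average linkage (UPGMA)** on Euclidean distances in the 3-component
  embedding (not on the raw RF dissimilarity), via
  `scipy.cluster.hierarchy`; verified against a naive O(n³) oracle.  Cuts
  are renumbered by descending cluster size (cl1 largest; ties by first
  appearance) for stable reporting.

## Model selection

Thirteen internal validity indices vote over k ∈ [2, 15] (the upper bound
comfortably exceeds the 10-cluster solutions seen in practice).  Rules:
maximize (Calinski–Harabasz, Dunn, silhouette, point-biserial, Gamma,
Ratkowsky–Lance), minimize (Davies–Bouldin, C-index, McClain–Rao,
Xie–Beni), largest successive decrease for the monotone dispersion indices
(Ball–Hall, trace-W), and the H ≤ 10 rule for Hartigan.  An index with no
finite optimum abstains and leaves the tally.  Winner = modal vote, ties
toward smaller k; the second mode is reported as runner-up because a
dominant-but-coarse 2-cluster solution can hide finer structure worth
characterizing.  Clusters with fewer than 10 members are excluded (members
flagged, never reassigned) and the remainder renumbered by size.

## Characterization

Kruskal–Wallis (tie-corrected, χ² approximation; H defined as 0 on
all-identical input) for continuous variables; plain Pearson χ² without
continuity correction for categorical ones (this convention reproduces the
published cluster-table statistics to the printed precision).  Post-hocs:
Dunn-type rank comparisons on the pooled ranking with Holm adjustment
(continuous); pairwise sub-table χ² with Holm (categorical); both gated on
a significant omnibus at two-sided α = 0.05.  Effect-size maps fit, per
ROI, `measure ~ cluster-membership + age + field strength + cohort
(+ eTIV for volumes)` over cluster ∪ HC, apply Benjamini–Hochberg across
the 41 ROIs, and report pooled-SD Cohen's d on age-adjusted measures only
where q < 0.05, signed so that positive d = more atrophy in the cluster.
Transition analysis cross-tabulates two solutions on shared subjects
(excluded members dropped) with Pearson χ² and the adjusted Rand index.

## Longitudinal model

`outcome ~ time * cluster * age_c + (1 | subject)`, REML, with time in
years from baseline and age mean-centered at baseline (centering
stabilizes the three-way interaction; all lower-order terms included).
The omnibus time×cluster effect is a Wald χ² over every fixed term
containing both factors.  Per-cluster slopes at the mean age get
Tukey-adjusted pairwise contrasts via the studentized range with residual
degrees of freedom.  Marginal means are fixed-effect predictions at the
mean age with delta-method SEs.  Non-convergence is reported, never
silently repaired; zero-variance (noise-free) fits hit the boundary and
are flagged non-converged even though the fixed effects are exact —
marginal means then warn instead of refusing.  Random slopes, non-linear
trajectories and informative dropout are out of scope (attrition treated
as missing at random).

## Synthetic cohort generator

The generator emulates a pooled four-cohort PD/HC sample (315/151, 107/44,
136/0, 75/38 PD/HC at full scale; mixed 1.5 T/3 T scanners; two cohorts
with up to 7 annual visits).  Feature model per subject:

```
x_j = [μ_j (1 + 0.8 (eTIV/1.5e6 − 1))_volumes] · s · g  −  pattern_j
      + cohort offset_j + 3T offset_j + ε_j
```

where `s` is the subtype's global atrophy scale, `g ~ N(1, 0.03)` a
per-subject global jitter, `pattern_j` the subtype's extra regional
atrophy (in HC-sd units), offsets are drawn per feature at the configured
sd (also HC-sd units), and `ε_j ~ N(0, sd_j)` with HC reference values
μ = 2.5 mm, sd = 0.15 mm for thickness and cohort-plausible subcortical
volumes with 10% sd.  eTIV ~ N(1.5e6, 1.5e5) mm³; WM-hypo is log-normal,
scales with eTIV and grows with atrophy burden.  Clinical covariates
(age, UPDRS-III, MoCA, MCI, H&Y, RBD) are coupled to the atrophy deficit
so severity subtypes show the expected age/motor/cognition gradient.
Longitudinal scores follow `baseline + slope·t + b_i + ε` with monotone
per-visit dropout (default 8%).

Calibration choices made once: severity preset scales 1.0/0.85/0.70
(15-point gaps), typicality preset three patterns of 6 ROIs each at 2.0 HC-sd
and matched scale 0.9, and global jitter sd 0.03 — small enough that a
15-point severity gap stays recoverable (ARI ≥ 0.8), large enough that
severity is a real nuisance.  The typicality *experiment* raises the
jitter to 0.05, the designed severity-nuisance level at which the benefit
of the adjustment is visible rather than marginal.  What the generator
does **not** emulate: hemispheric asymmetry (hemispheres are averaged
anyway), spatially correlated noise, scanner×region interactions,
non-Gaussian site effects, and realistic missingness patterns — so passing
recovery tests demonstrates internal consistency of the pipeline under its
own assumptions, not performance on real scanners.

## Verification experiments and problem sizes

The verification suite (and `scripts/acceptance.py`) uses reduced sizes
chosen to keep a full run in the minutes range: ~300 PD / 500-tree forests
and 10 seeds for the clustering experiments, ~600 subjects for
harmonization recovery (offsets injected at 2 HC-sd, one offset type at a
time — scanner mix differs by site, so simultaneous injection confounds
the two sequential residual steps), 5×300 subjects for slope bias, and 200
replicates of 60 subjects × 4 visits for the type-I error of the
time×cluster test.  Published-statistic reproduction uses the printed
count tables directly and is exact to rounding.

## Known limitations

* The ensemble vote is noisy at small n (≲150 PD): with few subjects the
  runner-up frequently displaces the winner, mirroring the instability of
  per-cohort solutions seen in practice.
* The sequential residual chain cannot fully separate scanner from site
  effects when a scanner type exists in only one site; the within-cohort
  estimator reduces but does not eliminate this.
* Wald tests and studentized-range contrasts use large-sample df; at very
  small per-cluster longitudinal counts they can be mildly anticonservative.
* The 13-index registry implements the voting semantics of the larger
  index families but not every published index.
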