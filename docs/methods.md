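# Methods

## Scope and data model

`coldscore` evaluates cold resistance in a panel of genotypes measured for a
set of positive, ratio-scaled traits under exactly two treatments: a control
(default label `CK`, 22 °C) and a cold stress (default `LT`, 10 °C), with
replicated measurements per (genotype, treatment, trait) cell. The on-disk
interchange format is a tidy CSV (`genotype,treatment,replicate,trait,value`)
plus a trait registry CSV declaring, per trait, its category, units, whether
it is strictly positive, and its **direction of association** with
resistance. All downstream quantities are computed from per-cell arithmetic
means over replicates — the coefficients are defined on a single value per
genotype and treatment, so averaging first is the natural reading and keeps
replicate noise out of the ratio's denominator asymmetrically.

Validation is strict by default: unknown treatment labels, traits absent
from the registry, non-numeric values (reported with their row number) and
non-positive values of ratio-scale traits are errors, as are genotypes
missing any (treatment, trait) cell — the comprehensive score averages a
fixed trait set, so a partial genotype cannot be scored. An opt-in flag
drops incomplete genotypes listwise instead.

## The evaluation chain

Per trait *i* and genotype *j*, with treatment means `T_CKij`, `T_LTij`:

* rate change `RC_ij = (T_LTij − T_CKij)/T_CKij × 100%`;
* cold-resistance coefficient `CRC_ij = T_LTij/T_CKij` (so
  `CRC = 1 + RC/100` identically, which the tests assert);
* membership `U_ij = (CRC_ij − CRC_i,min)/(CRC_i,max − CRC_i,min)` for
  direction +1, `1 −` that quantity for direction −1;
* comprehensive score `U_j = mean_i U_ij`;
* `CV_g = SD/mean × 100%` of genotype means, per trait and treatment.

Design choices where the method statement leaves room:

* **Direction registry.** The membership inversion requires knowing which
  traits rise with damage. The shipped default marks malondialdehyde,
  superoxide production, H₂O₂ content and intercellular CO₂ as
  damage-indicating (−1) and all other 25 traits as resistance-supporting
  (+1); the assignment follows the physiology (lipid peroxidation, ROS
  accumulation, and the stomatal-closure-driven Ci rise under cold) but is
  an assumption, so the registry is a plain CSV the user can override.
* **Degenerate traits.** If a trait's CRC is identical for every genotype
  the min-max normalisation is undefined. Such traits carry no ranking
  information, so all genotypes receive U = 0.5 with a logged warning; this
  keeps them from pulling `U_j` toward either extreme while preserving the
  trait count. Real cohorts essentially never hit this branch.
* **CV convention.** Sample (n−1) SD, because the panel is a sample of
  germplasm; `ddof=0` switches to the population convention.
* **RC summaries.** Cohort-level rate changes are reported both as the mean
  of per-genotype RC values (the default headline) and as the RC of the
  grand means; the two differ slightly whenever genotype effects and cold
  responses correlate.
* **Unweighted score.** `U_j` is the plain mean over traits; no
  PCA-loading or other weighting is applied (weighted variants exist in the
  literature, but the unweighted mean is the method implemented here), and
  a trait-subset option supports sensitivity analyses.

## Classical statistics

* **ANOVA.** Fixed-effects two-way factorial (genotype, temperature,
  interaction) computed closed-form on the balanced design; `F = MS/MS_res`
  with p from the F distribution. Unbalanced designs are refused with an
  explicit error rather than silently switching to a Type-II/III
  decomposition; one-replicate cells are refused for lack of residual df.
  If the residual mean square is zero (all values equal) F and p are
  reported as not applicable. The implementation is cross-checked against
  statsmodels' `anova_lm` in the tests.
* **Correlations.** Pearson r across genotype means within one treatment;
  two-sided p from `t = r√(n−2)/√(1−r²)`; counts of significant pairs at
  0.05 and 0.01 are reported uncorrected (the conventional reporting for
  such trait screens) per treatment and pooled. Zero-variance traits yield
  missing correlations with a warning.
* **PCA.** Eigendecomposition of the trait correlation matrix (PCA on
  standardized variables). The default observation set pools genotype ×
  treatment mean rows; per-treatment and CRC-matrix scopes are available
  since the published analysis does not pin this down. Components with
  eigenvalue strictly greater than 1 are "retained". Loadings are the
  orthonormal eigenvectors with a deterministic sign convention (largest
  coefficient positive). Cross-checked against scikit-learn.

## Classification

Agglomerative clustering of the genotype rows of `U_ij` (scipy), Euclidean
distance with Ward linkage by default — the linkage is a free choice since
only the clustering tool, not its settings, is on record; average, complete
and single linkage and city-block/correlation distances are exposed for
sensitivity analysis. The tree is cut into k = 4 clusters by default;
clusters are ranked by descending mean `U_j` and labeled I (strong) through
IV (sensitive), ties broken by the lower first-genotype index for
determinism. A newick export of the dendrogram is provided.

## qPCR

Relative expression by 2^−ΔΔCt with a single reference gene: replicate Ct
values are averaged per condition before the double subtraction; an SD over
per-replicate fold changes is attached for error bars. No
amplification-efficiency (Pfaffl) correction.

## The synthetic-cohort generator

The generator emulates the study design — default 39 genotypes × 29 traits
× 2 treatments × 3 replicates — with a multiplicative log-normal model:

    value(g, t, r, i) = baseline_i · G(g,i) · [m_i · I(g,i)]^(t=LT) · ε

* `baseline_i`: control-condition cohort mean. Where a cold-treatment
  cohort mean is on record (e.g. membrane stability index 66.07%, net
  photosynthesis 5.52 μM m⁻² s⁻¹, putrescine 274.89 nM g⁻¹ FW) the baseline
  is that value back-transformed through the cold multiplier; the remaining
  baselines are round values on realistic scales for maize seedlings.
* `m_i = 1 + RC_i/100` from the published cohort-mean rate changes (29
  values, from −48.6% for seedling length to +311.8% for proline).
* `G(g,i)`: mean-one log-normal genotype effect at the published
  control-treatment `CV_g` per trait.
* `I(g,i)`: genotype-specific cold response. A scalar latent resistance
  `z_g ~ N(0,1)` per genotype is mapped to `exp(d_i·γ·z_g)` (d_i the
  trait's direction, γ = 0.15 by default) plus mean-zero log-normal
  interaction noise (CV 0.05). The realized multipliers are renormalised to
  arithmetic mean 1 per trait — the standard factorial identifiability
  constraint — so the cohort-mean rate change stays pinned to the
  configured `m_i` while genotypes still differ coherently across traits.
  Resistant genotypes thus hold +1 traits closer to control levels and
  accumulate less damage, making `U_j`, the classification and the latent
  gradient mutually recoverable.
* `ε`: mean-one log-normal replicate residual, CV 0.03 — a free choice, as
  no within-genotype variance is on record.

All draws come from a single seeded `numpy.random.default_rng` stream in a
fixed order (latent scores → genotype effects → interaction noise →
residuals), so seeds are portable and output is bitwise reproducible.

What the generator does **not** emulate: assay mechanics (absorbances,
conductivities — trait values are emitted directly), bounded supports (the
membrane stability index is generated log-normally and can in principle
exceed 100%), trait–trait correlation beyond what the shared latent
gradient induces, and non-multiplicative replicate error. Tests passing on
synthetic cohorts therefore demonstrate the pipeline's correctness and
recoverability under this model, not distributional fidelity to any real
panel.

## Numerical and size choices

Default problem sizes keep the whole suite fast: the calibration and
recovery tests use the 39-genotype default cohort (one uses 390 to show
bias shrinkage), the CV-recovery check averages 20 seeds, and the ANOVA
type-I-error simulation runs 500 small (8 × 2 × 3) null designs
vectorised through the closed-form decomposition. Membership arithmetic is
exact up to floating point; comparisons in tests use absolute tolerances of
1e-9–1e-12 for algebraic identities and the documented statistical bands
for stochastic recoveries (±3 percentage points on cohort-mean rate
changes at n = 39; 25% relative on CV_g; |Spearman| ≥ 0.8 for type
recovery).

## Known limitations

* The membership ranking is panel-relative: adding or removing a genotype
  changes every trait's CRC extrema and hence every score; `U_j` values are
  comparable only within one cohort.
* The ANOVA is fixed-effects on balanced designs only; no mixed models, no
  heritability estimation.
* Direction assignments for membership inversion are a documented
  assumption, overridable per registry.
* The four-type split depends on the (configurable) linkage and metric;
  with defaults it is deterministic but not guaranteed to match any
  particular published grouping.
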