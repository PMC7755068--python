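# Methods

This note documents the statistical models implemented in `wheatgp`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Reaction-norm models

Records are line × environment observations `y_ij` (for the anther-count
trait these are per-trial BLUEs; the visual score enters on raw
per-environment values). All seven models are Gaussian random-effect models
over the same record vector, differing only in which covariance structures
are present:

| model | terms                        |
|-------|------------------------------|
| 1     | E + L                        |
| 2     | E + L + G                    |
| 3     | E + L + G + G×E              |
| 4     | E + L + A                    |
| 5     | E + L + A + A×E              |
| 6     | E + L + G + A                |
| 7     | E + L + G + A + G×E + A×E    |

with record-level covariances `Z_E Z_E′ σ²_E` (environment), `Z_L Z_L′ σ²_L`
(iid line), `Z_L G Z_L′ σ²_g` and `Z_L A Z_L′ σ²_a` (genomic and pedigree
main effects), `(Z_L K Z_L′) ∘ (Z_E Z_E′) σ²_{kE}` for the interactions
(zero covariance between records in different environments; PSD by the
Schur product theorem), and an iid residual. The iid line term L is kept in
every model alongside g/a, as the model sequence defines it. Environment
effects are random by default (three levels is few, but fidelity comes
first); `env_fixed=True` switches the E block to a flat prior.

### Estimation

Each record-level kernel is eigendecomposed once, `K_t = U_t D_t U_t′`, and
the term effect is written `u_t = U_t b_t`, `b_t ~ N(0, σ²_t D_t)`. Because
the columns of `U_t` are orthonormal, the Gibbs full conditional of `b_t`
is diagonal; a sweep costs two matrix–vector products per term. Structured
fast paths avoid dense eigendecompositions for one-hot main effects
(analytic), line kernels with equal record counts per line (via the
line-level eigensystem), and interaction kernels with at most one record
per line and environment (per-environment blocks); anything else falls back
to a dense `eigh`. The decompositions depend only on the record set and the
kernels, so cross-validation refits with different response masks share one
precomputation.

Variances carry scaled-inverse-χ² priors with df = 5 and scales set so each
term's prior mode is `prior_r2 · var(y_obs) / n_terms` (residual:
`(1 − prior_r2) · var(y_obs)`), `prior_r2 = 0.5` — weakly informative
defaults, since no sampler settings are inherited from anywhere. Default
chain: 12,000 sweeps, 2,000 burn-in, thinning 5; the recovery and
cross-validation analyses in the test-suite/acceptance script use shorter
chains (500–2,500 sweeps) after checking that posterior summaries are
stable at those lengths for these data sizes. Held-out responses are
sampled from the posterior predictive each sweep (data augmentation), so
masked-record predictions are posterior means of `μ + Σ u_t` at those
records. A single integer seed drives the whole chain; identical seed and
inputs give bitwise-identical summaries.

`solve_gblup_fixed_variance` provides the deterministic check: at fixed
variance components the posterior mean equals the Henderson mixed-model
solution `μ̂ = (1′V⁻¹1)⁻¹1′V⁻¹y`, `û_t = σ²_t K_t V⁻¹(y − μ̂)`. The sampler
run with variance sampling disabled must reproduce it; the intercept and
the environment effects are compared as a sum because with few environments
they are only jointly well identified.

### Prediction

`predict` sums posterior-mean effects looked up by environment, line, and
line-environment cell; terms with no information for a new record (an
unseen environment's E, an unseen line's L, an unobserved interaction cell)
contribute zero. Within-environment Pearson accuracy is invariant to
environment-constant shifts, which is why CV0 (predicting a whole unseen
environment) is scored fairly even though that environment's main effect is
unidentified.

## Kernels

* Genomic relationship: doses centered by `2p_m`; the default denominator
  is `2 Σ 2p_m(1−p_m)` as the source construction prints it, with
  `scale="vanraden"` (`Σ 2p_m(1−p_m)`) available — the two differ by an
  exact factor 2 that is absorbed by the attached variance component.
  Analyses that interpret σ² on the trait scale (the simulator recovery
  checks, GWAS kinship) use the VanRaden scale, under which the mean
  diagonal is ≈ 1.
* Missing doses are imputed by the per-marker mean dose `2p_m` before G
  (frequencies computed on non-missing calls are unchanged by this).
* Marker QC order: polymorphism (more than one observed genotype class and
  a segregating allele) → missingness ≤ 50% → MAF ≥ 5%, with the boundary
  MAF retained (the rule removes markers strictly below threshold); an
  optional genetic map restricts to mapped markers.
* Pedigree A: tabular method, unknown parents treated as unrelated
  non-inbred founders; cycles are rejected with the offending lines named.
* A ridge of 1e−8 is *not* silently added; kernels are checked PSD via the
  smallest-to-largest eigenvalue ratio (tolerance −1e−8).

## Variance components and heritability

REML throughout, with non-negativity enforced by box constraints on the
profiled restricted likelihood. Balanced complete grids (the common case
for designed trials and for the simulator) use the exact orthogonal-
contrast reduction: the restricted likelihood depends on the data only
through per-stratum sums of squares, making estimation O(#strata) per
objective evaluation; unbalanced data use a dense generic path (practical
to a few thousand records). For balanced data with interior solutions this
coincides with the ANOVA expected-mean-squares estimator, which the tests
use as an independent oracle. Within-trial BLUEs treat genotypes as fixed
and replicates (plants/spikes — the trials are unreplicated at the plot
level) as random, solved by GLS with Woodbury identities; with balanced
replication the BLUE is the line mean.

Heritability at the trial-mean level: `H² = σ²_G/(σ²_G + σ²_e/r)` within a
trial; `σ²_G/(σ²_G + σ²_GE/l + σ²_e/(lr))` across `l` trials. Note the
across-trial value can exceed the within-trial one when σ²_GE is small
relative to σ²_e(l−1)/r — pooling environments averages error — so no
ordering between the two is asserted in general. Component significance
(when requested) uses restricted likelihood-ratio tests against zero with
the boundary mixture `0.5 χ²₀ + 0.5 χ²₁`.

## GWAS

`y = Wα + x_m b_m + u + e` with `u ~ N(0, K σ²_u)`; W holds an intercept
plus the first principal components of the centered dose matrix (default
3). The variance ratio `h = σ²_u/(σ²_u+σ²_e)` is estimated once by REML on
the null model through the eigendecomposition of K and reused for every
marker (P3D); exact per-marker REML is available but quadratic in panel
size. Each marker gets a GLS Wald test with Gaussian reference and a
per-marker residual scale, so with K = I and no covariates the scan
reduces exactly to ordinary least-squares regression — the oracle used in
tests. Marker R² is the proportional reduction in decorrelated residual
variance when the marker is added. The favorable allele is reported as
"counted"/"alternate" relative to the dose coding, since plain dose tables
carry no allele names (HapMap-like input does, and its dose counts the
second listed allele). LD decay: squared dose correlation for
same-chromosome pairs within a 100-marker adjacency window, smoothed by a
10-point moving average over distance, with the distance at which the
smoothed curve first crosses r² = 0.2 reported as the LD extent.

## Cross-validation

CV1 assigns lines to k folds (test lines have no training record
anywhere); CV2 assigns records to folds (test records usually keep
same-line records from other environments in training); CV0 is
leave-one-environment-out. Defaults are 5 folds × 20 replicates = 100
partitions per scheme. Fold sizes differ by at most one; partitioning is a
pure function of (seed, record set). Per-partition sampler seeds derive as
`seed + partition index`. Accuracy is the plain within-environment Pearson
correlation — not standardized by √H², matching the accuracy tables being
reproduced. Environments with fewer than three test records are skipped
with a warning; constant predictions give a missing value, never zero.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
wheat biology:

* **Pedigree**: founders plus `n_generations` rounds of random crossing,
  parents drawn from all earlier individuals — full-sib/half-sib/deeper
  relationships accumulate, as in an advanced breeding panel. Defaults (50
  founders, 4 generations) are placeholders for an undocumented real
  pedigree depth, not estimates of it.
* **Markers**: founder haplotype alleles are independent Bernoulli draws at
  frequencies Uniform(0.1, 0.9) (chosen so monomorphic markers do not
  dominate QC); descendants are gene-dropped with Haldane recombination (no
  interference — the simplest standard map function). Founder LD is
  therefore nil: LD in descendants arises purely from co-inheritance, so
  the panel has weaker long-range LD than a real elite population.
  Designed-LD tests inject explicit founder genotypes.
* **Phenotypes**: `y_ijk = μ + E_j + g_i + gE_ij + ε_ijk`. The line value
  g has a marker-driven part (fraction `prop_additive_marked`, default 0.7,
  of σ²_G — a polygenic trait whose markers tag most but not all genetic
  variance) plus an iid line residual. The interaction gE is built from
  independent environment-specific marker effects, i.e. covariance
  `G σ²_GE` within an environment and zero across environments — the
  reaction-norm structure models 3/5/7 assume, and the structure required
  for their interaction variance to be recoverable. Every effect vector is
  centered and rescaled so its realized variance equals the requested
  component exactly, making recovery tests sharp: REML/posterior estimates
  then differ from the targets only through model misspecification (the
  iid-line REML model ignores kinship among lines, a few-percent effect at
  50 founders) and estimation noise. Default components are the combined
  anther-count analysis values (σ²_G = 211.09, σ²_E = 182.70,
  σ²_GE = 80.45, σ²_e = 185.03; 603 lines × 3 environments × 5 replicates,
  grand mean 57.31).
* **Planted QTL** (`n_qtl > 0`) concentrate the marker-driven variance on a
  chosen number of markers for association power checks.
* One integer seed expands into independent substreams per stage, so each
  stage is reproducible in isolation.

Not emulated: dominance/epistasis, selection and drift across cycles,
realistic genome content, ascertainment bias of array markers, founder LD.
Passing tests therefore demonstrate correctness of the estimation machinery
under the assumed generative structure, not performance on real wheat data.

### Problem sizes used in tests and the acceptance script

Marker panels are scaled to 1,000–2,000 SNPs (the `SimConfig` default stays
10,000) and cross-validation ordering checks run models 1–2 with 2
replicates × 5 folds at 500-sweep chains; variance-component recovery uses
the full 600 × 3 × 5 record set. These sizes were chosen as the smallest at
which the checked contrasts are stable across seeds.

## Numerical notes

* REML optimizers: L-BFGS-B on variances with bounds [0, ∞); analytic
  gradients on the dense path; method-of-moments starts.
* Eigenvalues below 1e−9 of the largest are truncated from kernel
  decompositions; eigendecompositions symmetrize their input first.
* Gibbs update order is fixed (intercept, then terms in model order, then
  variances, then masked responses) and records are processed in input
  order — determinism over speed.
* Ties in cross-validation fold sizes go to the earliest folds.
* Degenerate inputs: constant records yield all-zero variance components;
  monomorphic panels are a hard error for G; fully-missing markers are
  named in the imputation error; empty QC results warn rather than raise.

## Known limitations

* The unbalanced REML path is dense (O(n³) per evaluation) and intended
  for records in the low thousands; bigger unbalanced data should be
  collapsed to cell means first.
* The Gibbs sampler reports posterior means only; interval summaries must
  be computed from `chains_`.
* The A matrix ignores inbreeding of founders and selfing; the generator
  never selfs.
* GWAS assumes a single record per line (use BLUEs); multi-trait and
  multi-locus models are out of scope.
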