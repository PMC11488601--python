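# Methods

This note documents the statistical model, the inference machinery, the
synthetic-cohort generator, and the numerical and design choices behind
`gutbrainmap`, in the spirit of a model-description vignette.

## The per-voxel model

For subject i and voxel v, the outcome is modeled as

    y_iv = α_v + Σ_f β_fv · ln(max(RA_if, 10⁻³)) + γ_v'·(sex_i, age_i, BMI_i) + ε_iv.

Design choices feeding this model:

- **Flooring at 10⁻³.** Relative abundances below 10⁻³ are replaced by
  10⁻³ before the log transform; otherwise near-zero RAs yield log values
  approaching −∞ that dominate any least-squares fit. Rows are *not*
  re-closed to sum 1 after flooring: re-normalization would perturb the
  abundance ratios that the log-linear coefficient patterns encode
  (β_A ≈ 1, β_B ≈ −1 reads as the log ratio RA_A/RA_B).
- **Prevalence filter.** A family enters the design only if at least 5% of
  subjects carry it above 1% RA (inclusive on the 5% fraction, strict on
  the 1% abundance). The filter is evaluated on the un-floored table;
  since the floor (10⁻³) sits far below the 1% threshold the order is
  immaterial. Rare families carry almost no information after flooring and
  would only add noise columns to the Ridge fit.
- **Standardization.** All design columns (log-RAs and covariates) are
  standardized to mean 0, sd 1 so a single Ridge penalty λ is commensurable
  across regressors. The per-column means/sds are retained; reported
  coefficients are back-transformed to the log-RA scale (sign-preserving).
  Zero-variance columns are dropped with a warning. Within cross-validation,
  standardization is recomputed from each training fold alone.
- **Voxel mask.** Analysis is restricted to voxels with appreciable tissue
  signal: mean image (across subjects) above 10% of its robust maximum
  (98th percentile). A user-supplied mask is honored verbatim.

## The RSS-ratio statistic

Association strength at a voxel is RSSratio = RSS_cov / RSS_full, where both
terms are 10-fold cross-validated residual sums of squares: the reduced
model uses the covariates only, the full model adds the family block, and
both are Ridge fits sharing one fold assignment (so fold noise cancels from
the comparison). Ratios above 1 mean the microbiota improve held-out
prediction; under the null the CV estimation cost of the family block makes
ratios hover at or slightly below 1, which is the statistic's built-in
protection against overfitting.

- **Penalty selection.** The penalty is chosen per training fold by GCV over
  a 20-point log-spaced grid on [10⁻³, 10³], ties broken toward the larger
  (more conservative) penalty. GCV-within-the-training-fold costs one pass
  of matrix products given the fold's SVD; a nested inner-CV rule is
  available behind the same interface (`lambda_rule="inner_cv"` via
  `select_lambda`), and both keep selection strictly inside the training
  part. The covariate-only model is also a Ridge fit with its own
  GCV-selected penalty. Whether the original analysis penalized covariates
  or how it chose λ is unknown; both are config-visible choices here.
- **Implementation.** All voxels share the design, so the per-fold Ridge
  solutions for every voxel and penalty reduce to matrix products against a
  per-fold SVD (`CVPlan`). The factorization is computed once and reused by
  every permutation replay; chunked evaluation is numerically identical to
  per-voxel loops (tested to 10⁻¹² relative, the BLAS reassociation limit).
  Rank-deficient designs at λ = 0 fall back to the minimum-norm solution.

## Permutation inference

The null at a voxel is "the family block adds nothing beyond the
covariates". Surrogate outcomes are built from the covariate-only OLS fit
(γ̂, residuals ε̂) and a subject permutation, and the *entire* statistic
pipeline — CV, standardization, penalty selection — is rerun per surrogate.
Permutation 0 is always the identity, so the observed statistic is counted
in its own null and the smallest attainable p is 1/B (0.004 at B = 250).

- **Orthogonalized residual permutation (default).** The textbook
  Freedman–Lane surrogate y* = Zγ̂ + Pε̂ converts the covariate-aligned part
  of the noise (≈ q/n of its energy, q = 4 here) into signal that every
  surrogate's covariate model can fit consistently, while the observed data
  pays it as estimation noise. For pivotal statistics this cancels; the
  CV-RSS ratio is not pivotal, and at n = 40 the imbalance measurably
  deflates the surrogate numerator (null mean p ≈ 0.41). The pipeline
  therefore permutes the residuals inside an orthonormal basis Q of the
  orthogonal complement of the covariate space: y* = Zγ̂ + Q P Q'ε̂. Every
  surrogate (including the identity, which reproduces y exactly) then has
  the identical covariate-aligned component and identical residual energy,
  and Q'ε is exactly i.i.d. under Gaussian errors, so the statistic is
  exchangeable across permutations. The textbook scheme remains available
  (`perm_scheme="freedman_lane"`), and the `freedman_lane_surrogate`
  function implements it verbatim.
- **TFCE.** The enhanced quantity is s = max(RSSratio − 1, 0): null ratios
  center near 1 and TFCE needs a nonnegative statistic anchored at 0. The
  enhancement integrates extent^E × height^H over thresholds with the
  de-facto standard parameters E = 0.5, H = 2, 26-connectivity, and step
  dh = (map max)/100, each map (observed and permuted) integrated with its
  own step. All parameters are exposed in the config. Supra-threshold
  comparisons use `s ≥ h − ε` with ε = 10⁻⁹·dh so a voxel exactly at a
  threshold is never lost to float rounding.
- **p-maps.** Uncorrected p at a voxel counts permutation ratios reaching
  the observed ratio; FWE p counts permutation map-maxima of TFCE reaching
  the observed TFCE. The FWE map is clipped from below at the uncorrected
  map (the elementwise maximum of two valid p-values remains a valid,
  slightly conservative FWE p), enforcing the expected dominance
  p_FWE ≥ p_uncorrected at every voxel.
- **Staged budgets.** Permutation b is a pure function of (master seed, b),
  so a 50-permutation run extended by 200 reproduces a single 250-run
  bit-for-bit. For n ≤ 7 permutation units the scheme enumerates all n!
  permutations exhaustively instead of sampling.
- **Reporting.** Surviving voxels are grouped by connectivity; each cluster
  reports its peak (maximum ratio; ties resolve to the lexicographically
  smallest voxel index), size, world coordinates via the affine, and p.
  Two regimes: FWE < 0.05 (primary) and uncorrected p < 0.004 with
  ratio > 1.33 (exploratory; 1.33 marks a >25% held-out RSS reduction).
  Empty reports are legitimate.

## Post-hoc analyses

- **Family contributions.** At each reported peak the full-data Ridge model
  is refitted (GCV penalty) and the coefficients reported per family with
  sign, on the log-RA scale. Each family's p-value comes from its own
  residual-permutation null: the nuisance model for family f keeps the
  covariates *and all other families*; its residuals are permuted (same
  permutation stream and budget as the voxelwise inference) and the full
  model refitted with the penalty held at the observed GCV choice. Two
  design points matter and were verified by simulation: (i) a global-null
  surrogate (destroying all family signal) distorts every coefficient's
  null at a signal voxel — uninvolved families looked significant with
  re-selected penalties and over-conservative with fixed ones — whereas the
  per-family nuisance leaves an uninvolved family's p uniform; (ii) holding
  the penalty fixed removes the adaptive-shrinkage asymmetry between
  observed data (signal present) and surrogates. The tiered labels
  (<0.01, <0.001, <10⁻⁶) describe the attainable classes; permutation
  granularity bounds p from below at 1/B.
- **Subgroup reruns.** RSS ratios at the reported peaks are recomputed
  within a subject subgroup (e.g. BMI > 25, nonsmokers) with folds freshly
  assigned from the same fold seed — so the full-cohort "subgroup"
  reproduces the original assignment and yields deltas of exactly zero.
  Subgroups below 2K subjects are refused: 10-fold CV on fewer than 20
  subjects is not meaningful. Note that smaller subgroups systematically
  lower CV ratios (higher estimation cost), so deltas are expected to be
  slightly negative even in homogeneous cohorts.
- **Clinical correlations.** Plain Pearson correlations between per-subject
  peak values and clinical scores, on pairwise-complete observations
  (clinical instruments have per-test missingness; no imputation).
  Benjamini–Hochberg q-values span all peak × score tests of the run; the
  report flags q < 0.05 and nominal p < 0.05 separately. Correlations are
  not partialed on the covariates (a config-visible choice); constant
  vectors are excluded from the BH family with a warning.

## The synthetic cohort generator

The generator defines the study conditions the tests exercise.

- **Abundances.** Log-normal intensities closed to the simplex (chosen over
  a Dirichlet because the analysis presumes heavy-tailed, *correlated*
  compositions). Common families get location parameters linearly spaced on
  the log scale from +2 to −2 (a few dominant taxa, a long tail), unit log
  sd; families 0 and 1 are collinear on the log scale (log-intensity sd 0.2
  apart), the multicollinear case Ridge exists for. A configurable fraction
  (default 0.3) of families is rare, with intensities at 3×10⁻⁵ of the
  expected total so that after closure >95% of their values fall below the
  10⁻³ floor.
- **Images.** A brain-like ellipsoid (semi-axes 0.45 × shape) carries
  baseline 100 plus covariate effects (default slopes 0.5 / 0.02 / 0.03 for
  sex / age / BMI) plus Gaussian noise (default sd 1); outside the
  ellipsoid the intensity is near zero so mask construction is meaningful.
  Planted spherical clusters add Σ_f β_f ln(max(RA_f, 10⁻³)); the default
  planted pattern is β = (+1, −1) on two prevalent families — the
  abundance-ratio pattern. The ground-truth record stores flat voxel
  indices, family indices and effect sizes, plus the affine (2 mm isotropic
  voxels by default).
- **Covariates and clinical scores.** Sex/age/BMI match a middle-aged,
  high-BMI cohort (69% female; age ≈ N(46.7, 10.7²) on [22, 66];
  BMI ≈ N(35.3, 10.9²) on [19, 63]). Each clinical score is
  c·z(region mean) + √(1−c²)·noise, so its population correlation with the
  planted region's mean signal equals c (default 0.4 when a cluster is
  planted); scores are on a standardized scale, not the instruments' raw
  ranges. Default cohort size is 133 subjects; scenarios below 20 subjects
  are rejected (10-fold CV becomes ill-defined).
- **What it does not emulate:** sequencing noise and taxonomic
  misassignment, MRI physics and preprocessing artifacts, spatial
  autocorrelation of the noise (voxel noise is independent), covariate–
  microbiome confounding, and non-Gaussian score distributions. Passing
  tests therefore demonstrate the statistics are correct and calibrated
  under the assumed generating model, not that real data meet those
  assumptions.

## Validation scales and reproducibility

Every random draw descends from one master seed through named streams
(folds, permutation b, scenario components), so identical config + seed
yields byte-identical tables. The validation suite uses problem sizes
chosen to give the checks statistical teeth at desk scale: type-I error is
measured over 200 global-null cohorts (n = 40, 100 families, 12³ images,
B = 100), with the family-wise rejection rate checked against the exact
binomial 99% interval around 0.05. The rejection rule there is the exact
permutation test's p ≤ α (size exactly α when αB is an integer); a strict
p < α rule would have size (αB − 1)/B = 0.04 at B = 100. Pooled
uncorrected p-values are checked
for uniformity via KS after a randomized-PIT transform (permutation p's are
discrete on {1/B, …, 1}; subtracting seeded U(0, 1/B) jitter makes them
exactly U(0,1) under the null, so the continuous KS test applies). Signal
recovery uses 20 cohorts with one 33-voxel planted cluster (β = 1 on two
families, noise sd 0.5, n = 80), scoring Dice overlap of the FWE < 0.05
voxels with the truth and top-3 identification of the planted families with
correct signs. TFCE is verified for exact equality against a brute-force
triple-loop flood-fill implementation on 4³ and 6³ maps across
E ∈ {0.5, 1}, H ∈ {1, 2} and 6/26-connectivity; both implementations share
only the threshold-ladder convention.

## Known limitations

- The orthogonalized permutation scheme is exactly exchangeable for
  Gaussian errors and approximate otherwise (as is Freedman–Lane itself).
- Contribution p-values are a permutation stand-in for an unspecified
  per-family test; their null holds the penalty fixed at the observed GCV
  choice.
- No spatial regularization across voxels, no elastic-net/lasso variants,
  no parametric (Gaussian-field) correction, and no mediation or causal
  modeling of the microbiota → brain → behavior chain.
- Voxels are processed in a single vectorized pass; plain process
  parallelism can shard cohorts (as the validation scripts do implicitly by
  cohort), but there is no built-in scheduler integration.
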