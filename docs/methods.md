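# Methods

This note documents the statistical model behind `mrchain`, the numerical
conventions the implementation fixes, what the synthetic-data generator does
and does not emulate, and the design choices made where the methodology is
genuinely open.

## Two-sample MR model

The package works entirely with GWAS summary statistics: per-variant effect
sizes, standard errors, and allele information for an exposure and an outcome
measured in non-overlapping samples. The instrumental-variable assumptions
are the usual ones — instruments associate with the exposure, are not
confounded with the outcome, and affect the outcome only through the
exposure. Violations of the third assumption (horizontal pleiotropy) are
what the robust estimators and diagnostics are for.

All estimators operate on per-variant Wald ratios. The default ratio SE is
first-order, `se_out / |beta_exp|`, which ignores the exposure-side sampling
error; a second-order option (`second_order=True` on the estimators) adds the
`beta_out^2 * se_exp^2 / beta_exp^4` term. In the F ≥ 10 regime the package
enforces by default, the difference is small; the first-order form is the
default because it matches standard two-sample practice.

### Estimators

- **IVW.** Weighted mean of ratios with inverse-variance weights. Fixed
  effects: `se = (sum w)^(-1/2)`. Multiplicative random effects: the fixed
  SE scaled by `sqrt(max(Q/(L-1), 1))` — floored at the fixed-effects
  variance so random effects can never claim more precision than fixed.
  `effects_model="auto"` (the pipeline default) chooses random effects
  exactly when Cochran's Q has p < 0.05 and records which branch fired in
  `extras["model_used"]`.
- **MR-Egger.** Weighted least squares of outcome betas on exposure betas
  with an intercept, weights `1/se_out^2`, after flipping each variant's
  allele frame so the exposure beta is positive (the fit is invariant to
  per-variant frame flips only after this orientation). The slope is the
  pleiotropy-adjusted effect; the intercept estimates mean directional
  pleiotropy under the InSIDE assumption. Inference uses a t reference with
  L−2 df. A perfectly collinear fit (zero residual) is given p = 1 for a
  zero coefficient rather than NaN.
- **Weighted median.** Ratios sorted ascending; standardized cumulative
  weights `p_j = (S_j − w_j/2) / S_L`; the estimate linearly interpolates the
  ratios at p = 0.5 (clamped to the extreme ratios outside `[p_1, p_L]`).
  SE from a parametric bootstrap: each ratio resampled from
  `Normal(r_j, se_rj)` with weights held fixed, default 1000 draws.
- **Mode estimators.** Normal-kernel density over the ratios, maximized on a
  512-point grid spanning the ratios ± 3 bandwidths. The default bandwidth
  is `0.9 * min(sd, 1.4826 * MAD) * L^(-1/5)` (MAD-based Silverman variant;
  falls back to the SD when the MAD is zero), scaled by a configurable
  `bandwidth_factor` (default 1). The weighted variant weights each kernel
  by the variant's IVW weight. A zero-spread degenerate input returns the
  common ratio directly. SE from the same parametric bootstrap (bandwidth
  recomputed per draw).

p-values use a normal reference everywhere except MR-Egger. Reported 95%
intervals use the conventional 1.96 multiplier (t quantile for Egger).

### Diagnostics

- **Cochran's Q** around the fixed-effects IVW mean, chi-square with L−1 df.
- **Egger intercept test**: the regression intercept with its t-test.
- **Leave-one-out**: IVW (auto) after each single-variant exclusion; a row
  is flagged when the exclusion flips the sign of the estimate or moves it
  outside the full-set CI. Output has L+1 rows (the last is the full set).
- **MR-PRESSO.** Observed statistic: `RSS = sum_j w_j (r_j − beta^(−j))^2`
  with leave-one-out IVW predictions. Null distribution: parametric
  simulation drawing `beta_exp* ~ N(beta_exp_j, se_exp_j)` and
  `beta_out* ~ N(beta_exp_j * beta^(−j), se_out_j)`, recomputing the
  leave-one-out RSS per draw; the global p-value is
  `(1 + #{RSS* ≥ RSS}) / (1 + n_sim)`, so it is never exactly zero.
  Per-variant outlier p-values compare each observed residual with its own
  simulated distribution as a raw exceedance fraction (zero allowed, meaning
  "beyond every simulation"); variants are declared outliers at
  `outlier_alpha` Bonferroni-corrected over L, and only when the global test
  is itself significant — outlier hunting in globally homogeneous data is
  not attempted, which keeps the null false-outlier rate at the global
  test's level. The distortion test compares the IVW estimate before and
  after outlier removal against a permutation distribution built by removing
  random same-size subsets of inliers; with no outliers it is reported as
  NaN. Defaults (`n_sim = 1000`, `outlier_alpha = 0.05` with Bonferroni)
  follow the method's original conventions. All Monte-Carlo draws come from
  one `numpy` Generator seeded explicitly and consumed in a fixed order, so
  results are platform-reproducible.

## Instrument selection and harmonization

Selection is p-value threshold (strict `<`; default 5e-8 forward, 5e-6
reverse, per-trait overrides supported), then greedy LD clumping (keep the
smallest-p remaining variant, drop same-chromosome variants within the window
whose r² exceeds the cutoff; defaults r² ≤ 0.001 within 10,000 kb), then the
weak-instrument filter F = β²/σ² ≥ 10 (F exactly 10 is kept). LD is supplied
by the caller — a pairwise r² matrix or a declaration of independence —
rather than queried from a reference panel, which keeps the algorithm intact
without a network dependency; proxy-variant substitution is likewise out of
scope, so variants absent from the outcome table are dropped with a logged
count.

Harmonization aligns the outcome to the exposure's effect-allele frame:
identical pairs pass through; swapped orientations negate the outcome beta
and reflect its allele frequency; complementary-strand representations are
re-complemented first. Palindromic variants (A/T, G/C) carry no strand
information in their alleles, so orientation is resolved by requiring both
allele frequencies to fall outside an ambiguity band around 0.5 — default
(0.42, 0.58), a conventional choice; within the band (or with a missing
frequency) the variant is dropped as ambiguous. Anything else is dropped as
incompatible. Every shared variant's disposition is recorded in a
harmonization report.

## Two-step mediation

β0 (exposure→outcome), β1 (exposure→mediator), and β2 (mediator→outcome) are
each estimated by univariable IVW with the auto effects model. Design
choices:

- **β2 is univariable**, not adjusted for the exposure via multivariable MR;
  every result carries this as a limitation note. The mediator's instrument
  set excludes variants already selected as exposure instruments, so the two
  steps use disjoint panels and an exposure→mediator→outcome path cannot
  masquerade as a mediator→outcome effect.
- **Screening**: a mediator whose β2 is not significant at `screen_alpha`
  (default 0.05) is flagged as screened out and no indirect effect is
  computed, mirroring how published analyses discard candidate mediators
  without an outcome effect.
- **Delta method**: `se_indirect = sqrt(b1^2 s2^2 + b2^2 s1^2)`, first-order,
  zero cross-covariance (non-overlapping samples); the `second_order` switch
  adds the `s1^2 s2^2` term.
- **Proportion CI**: the indirect-effect CI bounds divided by β0, returned
  ascending. This is the convention consistent with published
  proportion/CI pairs; a delta-method-on-the-ratio alternative was
  considered and not used because it is not what reconciles those printed
  tables. Proportions outside [0, 100] are flagged as inconsistent
  mediation, not raised as errors.
- **Display convention** (`report_mediation`): the indirect effect and its
  CI are rounded to 3 decimals first, and the displayed proportion (2
  decimals) is computed from those rounded values — the convention that
  reproduces printed mediation tables digit-for-digit. Full-precision values
  are always emitted alongside; rounding is half-away-from-zero, as printed
  tables use.

## Synthetic-data generator

`simulate_chain` draws, for L exposure instruments, per-allele effects
`gamma_j ~ N(0, gamma_sd^2)`; true marginal effects are `gamma_j` on the
exposure, `kappa * gamma_j` (plus optional mediator-specific pleiotropy) on
the mediator, and `(theta_dir + kappa*theta_M) * gamma_j + alpha_j` on the
outcome, with `alpha_j ~ N(pleio_mean, pleio_sd^2)` the horizontal-pleiotropy
path. A further `L_med` mediator-specific instruments carry
`delta_j ~ N(0, delta_sd^2)` on the mediator and `theta_M * delta_j` on the
outcome; they are what instruments the mediator→outcome leg, emulating the
mediator GWAS's own hits. Observed coefficients add independent noise with
the GWAS regression scaling `se = 1/sqrt(2 n maf (1−maf))`; allele
frequencies are drawn uniformly on `maf_range` and observed with their own
sampling noise; a configurable fraction of variants receives palindromic
allele pairs; `flip_fraction` re-orients outcome rows (for harmonization to
undo) and `missing_fraction` drops rows (exercising the inner join).
Variants sit 1 Mb apart on one chromosome so that `simulate_ld_blocks`'s
block-diagonal r² structure (blocks of consecutive variants) falls inside the
default clumping window for block sizes up to 10.

Defaults: `L = L_med = 100`, `n = 100,000` per GWAS, `kappa = 0.4`,
`theta_M = 0.5`, `theta_dir = 0.1` (total effect 0.3, true mediated
proportion 2/3), no pleiotropy, `maf_range = (0.05, 0.5)`, 15% palindromic
variants. Instrument effects default to `gamma_sd = delta_sd = 0.15`
(mean F near 10³ at n = 100k): the generator's job in the validation suite is
to represent the strong-instrument regime in which the ratio estimators'
no-measurement-error assumption holds and nominal CIs are approximately
calibrated. Lowering `gamma_sd` reproduces the weak-instrument regime, where
IVW acquires the well-known attenuation bias (amplified by √L relative to its
SE) and coverage degrades — useful for studying that behaviour, but not the
reference condition.

What the generator does **not** emulate: liability-threshold case-control
outcomes (binary-trait log-odds are treated as linear in the instrument
effects), realistic LD from haplotypes, winner's-curse distortion of
published instrument panels, sample overlap between GWAS, and
population-structure confounding. Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated generative model,
not robustness to those additional real-data features.

Because the generator emits instrument panels that are already
genome-wide-selected (every exposure instrument is drawn from its effect
distribution, not from a genome-wide screen on the same data), validation
runs set the p-value threshold open (1.0) and let the F ≥ 10 filter carry
selection; applying a p-threshold to the same table that generated the
instruments would add winner's-curse bias that the real two-stage design
avoids. Threshold behaviour itself is tested separately on fixed fixtures.

## Pipeline conventions

A direction is "supported" when the IVW p-value is below `alpha` (0.05
default; a Bonferroni option over the number of exposures exists and is off
by default, since the emulated workflow applies no formal multiplicity
correction) and the weighted-median estimate agrees in sign. A direction
whose selection or harmonization yields no usable instruments — typical for
reverse analyses against a weakly powered disease GWAS — is reported as
unsupported with the failure recorded rather than raised. Per-task seeds are
derived deterministically from the analysis seed and the direction label
(CRC32-based, below 2³¹), and report files are written with a fixed float
format, so a fixed configuration and seed reproduce every output byte for
byte.

## Validation problem sizes

The acceptance suite uses: 1000 replicates for IVW bias/coverage of the
total effect (L = 100, n = 100k); 2000 null replicates (L = 50) for the
IVW and Cochran-Q rejection rates; 100 replicates (L = 50, n_sim = 300) for
MR-PRESSO planted-outlier detection at a 10-ratio-SE displacement; and 100
replicates of the full two-step pipeline for mediated-proportion recovery.
These sizes put the Monte-Carlo error of each measured rate well inside the
asserted bands while keeping the whole suite to a couple of minutes.

## Known limitations

- No multivariable MR, Steiger directionality filtering, proxy-variant
  lookup, or liability-scale modelling; no remote GWAS retrieval.
- The mediated-proportion CI ignores the uncertainty in β0 (bound division),
  matching the convention of the published tables it reproduces.
- Genome positions are treated as opaque coordinates used only for clumping
  windows; no build liftover.
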