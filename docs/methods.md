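# Methods

## Model

Each data row is one effect size comparing an animal-pollinated treatment
arm with an auto-pollinated control arm, both summarised by (mean x̄, SD s,
n experimental units). Contrast-based analyses model the vector of effect
sizes y (lnCVR, lnVR or lnRR) as

    y ~ N(Xβ, V),    V = S + σ²_pub Z_pub Z_pubᵀ + σ²_comp Z_comp Z_compᵀ + σ²_eff I

where S is the known sampling variance–covariance matrix and the three
nested random levels are publication, experimental comparison and effect
size (the last is the residual heterogeneity; it is always present).
Nesting is enforced by building comparison keys as
`publication:comparison` compound labels. Arm-based analyses put one row per
arm, with response `ln s + 1/(2(n−1))`, sampling variance `1/(2(n−1))`,
and fixed effects for the treatment condition and `ln x̄`; a control arm
shared by several treatments contributes exactly one row.

### Effect sizes and bias corrections

The estimators are the small-sample bias-corrected forms: the `1/(2(n−1))`
terms correct the mean of `ln s` (from the chi distribution of s under
normality) and the `CV²/(2n)` terms correct the mean of `ln x̄` (delta
method). They satisfy, exactly and including corrections,
`lnCVR = lnVR − lnRR`, and each estimator is antisymmetric under swapping
the arms. The lnCVR sampling variance omits the mean–variance correlation
term of the fullest published estimator because two-arm summary data carry
no within-arm correlation estimate; it is exposed as
`mean_sd_correlation` for sensitivity. A second switch,
`variance_mean_terms=False`, drops the `CV²/n` terms from the lnCVR
variance, giving the pure log-SD weighting (see "Arm/contrast equivalence").

### Shared controls

Rows that compare different treatments to the same control group have
correlated sampling errors. The covariance is the control arm's full
contribution: `CV_C²/n_C` (lnRR), `1/(2(n_C−1))` (lnVR), their sum (lnCVR).
Blocks are assembled per shared-control key; the matrix is checked for
positive semi-definiteness via its smallest eigenvalue (tolerance
`1e−10 × largest`), with sub-tolerance rounding deficits repaired on the
diagonal. Effects of different types are never mixed in one matrix.

### Estimation

Variance components are estimated by maximising the REML (default) or ML
log-likelihood over log σ², with L-BFGS-B from three fixed start points
(0.1×, 1×, 10× the mean sampling variance), a Nelder–Mead polish, an
effective-zero floor of 1e−10 and objective tolerance 1e−8; β is the GLS
solution at the optimum. The likelihood is evaluated on the independent row
blocks implied by the random structure and the non-zeros of S. The REML
log-likelihood uses the convention that includes +½ log|XᵀX| (invariant to
reparameterisation; numerically identical to metafor's `logLik`). ML fits
are used for likelihood-ratio moderator tests, REML refits for reported
estimates. Fits are deterministic given inputs; a grid-search oracle test
pins the optimum to 4 decimals on small problems, and a metafor
cross-check pins estimates, SEs, variance components and log-likelihoods on
a shared-control fixture.

Inference uses normal (z) Wald statistics and intervals by default; the
arm-based analyses instead use bias-reduced (CR2-type) cluster-robust
covariance, clustered on the experimental comparison, with per-coefficient
Satterthwaite degrees of freedom and t intervals. The CR2 adjustment
rescales each cluster's residuals so that, under the fitted working
covariance, their outer product is unbiased for that covariance; with
every row its own cluster it reduces to the usual leverage-adjusted
heteroscedasticity-robust form (tested algebraically).

Prediction intervals widen the Wald interval by the summed random-effect
variances: `estimate ± z √(SE² + Σ_l σ²_l)`.

### Heterogeneity

I² uses the Higgins–Thompson typical sampling variance
`(k−1)Σw / ((Σw)² − Σw²)` with w = 1/v computed from the sampling-variance
diagonal (covariances ignored; a plain-mean estimator is exposed as an
alternative). Per-level shares are `100·σ²_l/(Σσ² + typical_v)` and sum to
the total. Marginal R² is `100·var(Xβ̂)/(var(Xβ̂) + Σσ²)` (n−1 denominator),
clipped to [0, 100].

### Model suite

`run_suite` fits: null models CVR0/SD0/RR0/VR0; crop (CVR1/SD1) and spatial
scale (CVR2/SD2) moderators; covariate models CVR3 (lnCVR ~ lnRR), CVR4
(lnCVR ~ z-standardised treated-arm yield) and RR1 (lnRR ~ z-standardised
control-arm yield); pollinator type (CVR5, six levels), open vs other
(CVR6) and pollination intensity on the high/low subset (CVR7). Categorical
moderators are fitted in cell-means coding for reported per-level estimates
and reference coding for the ML/LRT twin (identical likelihoods, tested).
In the arm-based moderator models the condition effect is interacted with
the moderator so each level gets its own stability coefficient.
Z-standardisation is within crop × response-measure × scale groups with the
n−1 SD; singleton or zero-spread groups give missing values and those rows
drop from the covariate model. Covariate models are univariate GLS fits
treating the covariate as fixed and error-free — no errors-in-variables
correction. Percent translations: stability `(1 − e^b)·100`, yield and
variance `(e^b − 1)·100`. "Plot" and "cohort" scales are one level
(`plot_or_cohort`); a `merge_plot_cohort` switch exposes the alternative.
The intensity subset is selected by the dataset's `intensity` flag rather
than re-derived, since the flag reflects experimental design, not a
computable rule.

### Sensitivity analyses

Leave-one-publication-out refits the null model once per publication;
one-effect-per-comparison keeps a uniformly drawn effect per comparison,
seeded; the time-lag test adds mean-centred publication year as a
continuous moderator; the Egger-type test regresses lnRR on `√(1/ñ)` with
effective sample size `ñ = n_T n_C/(n_T + n_C)` (the `4n_T n_C/(n_T+n_C)`
variant is exposed, since reports rarely state which was used).

## Synthetic data

The summary-level generator draws true row effects as
`μ + b_pub + b_comp + b_eff` with independent normal deviates per level,
realises them exactly at the distribution level (control units lognormal
with configured mean and CV; treatment units lognormal with mean
`m_C e^{lnRR}` and CV `cv_C e^{lnCVR}`), and computes arm summaries from
the finite unit samples, so sampling noise enters only through n. Defaults
emulate the pollination-stability evidence base: 47 publications, 3–6
comparisons each, 1–4 effect sizes per comparison (~500 effects), two
treatments per shared control, true lnCVR = ln(0.68) ≈ −0.386 (a 32%
stability gain), true lnRR = ln(2.04) ≈ 0.713 (a 104% yield benefit),
level variances {0.05, 0.02, 0.01} for lnCVR and {0.20, 0.05, 0.02} for
lnRR, and a coupling of −0.28 between lnCVR and lnRR deviations that
reproduces the observed negative stability–benefit association. Crops,
scales, treatment types, countries and years are assigned at realistic
frequencies; ~23% of publications are flagged as intensity experiments
(high/low arms), giving an intensity subset of roughly the observed size.

Unit yields are lognormal: yields are positive, right-skewed, and the
strong mean–variance relationship of real data motivates multiplicative
noise. Two consequences are documented deliberately:

- Control CV 0.3 and 8–40 units per arm are the defaults. The `1/(2(n−1))`
  correction is exact under normality; for lognormal units a residual
  kurtosis bias of order κ/(4n) per arm remains, ≈ +0.01 on pooled lnCVR at
  these defaults (verified by the recovery test, which bounds |bias| at
  0.02). Much larger CVs or much smaller n would push this residual up;
  that is a property of the estimator on skewed data, not of the generator.
- Seeding uses one master seed with per-entity substreams
  (publication/comparison/effect keyed), so enlarging counts never
  reshuffles earlier rows and repeat calls are byte-identical.

The ceiling generator draws a per-unit maximum potential yield
(lognormal, default mean 100, CV 0.2) and a pre-ceiling yield (default mean
50, CV 0.3, multiplied by the pollination gain in the treated arm), and
takes the minimum. As the gain pushes treated units into the ceiling their
relative variation compresses toward the ceiling's own CV, producing
negative lnCVR alongside positive, saturating lnRR — the resource-limitation
mechanism. A gain grid (1–4, 8 comparisons per gain) yields a dataset on
which the lnCVR-on-lnRR regression is reliably negative.

What passing tests on generated data do *not* show: robustness to
non-lognormal yield distributions, digitisation error, unit-conversion
heterogeneity between response measures, or selective reporting — none of
which the generator emulates (temporal series and spatial autocorrelation
are likewise out of scope).

## Numerical and design choices

- SE→SD conversion (`sd = se√n`) happens once at load; zero-SD rows are
  excluded with a logged warning because log-ratio measures are undefined
  for them.
- Rank deficiency of a design matrix is reported with the aliased columns;
  a constant covariate therefore fails fast.
- Degenerate CI level 0 gives a point interval; variance components at the
  1e−10 floor are reported as 0.
- Arm/contrast equivalence: the arm-based treatment coefficient equals the
  pooled lnCVR *exactly* only under matched weighting — equal arm sizes,
  variance components constrained to zero, SD-only lnCVR variance, and a
  bias-corrected log-mean offset `ln x̄ + CV²/(2n)` in the arm rows (so the
  treated-minus-control contrast reproduces the corrected lnCVR identity).
  All four switches exist and the equivalence is asserted to 1e−6; under
  default weighting the two analyses agree approximately, not identically.
- Problem sizes in the test suite (e.g. 200 recovery replicates at the
  47-publication structure, 10⁴ Monte-Carlo arm pairs, 20 ceiling seeds)
  were chosen to give decisive Monte-Carlo bounds while keeping a full run
  of the suite in single-digit minutes on one core.

## Known limitations

- The REML engine supports strictly nested random levels plus a known
  sampling covariance; crossed random effects (e.g. cultivar crossed with
  publication) are not implemented.
- Wald/z inference can be mildly anticonservative with few publications;
  the robust t path is available for arm-based models only.
- The Egger and time-lag tests are the only publication-bias diagnostics;
  trim-and-fill and selection models are out of scope, as are variability
  effect sizes for proportions and Hedges' g.
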