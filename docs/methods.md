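# Methods

This note documents the statistical models in `edumr`, the generating
process of the synthetic data, the numerical choices, and the known
limitations. Notation: E = years of education, C = standardised
cognitive score, S = a binary smoking outcome; β₁, β₂ are the direct
effects of E and C on S; α_E (SD per year) and α_CA (years per SD) are
the two mutually exclusive mediation paths E→C and C→E; U is a latent
confounder.

## Generating model (`edumr.simulate`)

Dosages for m = `n_snps_edu` + `n_snps_cog` independent SNPs are drawn
Binomial(2, pⱼ) with MAFs uniform on `maf_range` (default 0.05–0.45).
Weights are equal-contribution per SNP, scaled so the education score
explains `r2_edu` of the education variance and the cognition score
`r2_cog` of the cognition variance. The defaults r2_edu = 0.0046 and
r2_cog = 0.0074 were chosen so that the first-stage F at the default
cohort size of 120,050 lands near the values typical of strong
polygenic-score instruments in cohorts of this size (F ≈ n·r²/(1−r²),
i.e. in the 500–900 range); no published r² was available to match
directly.

Exposures (upstream first, per the active DAG):

    E = μ_E + G·w_E [+ α_CA·C] + c_E·U + σ_E·ε
    C =       G·w_C [+ α_E·(E−μ_E)] + c_C·U + σ_C·ε

with U ~ N(0,1) and residual SDs solved so the *nominal* SDs (2.4 years;
1 SD) hold when the mediation path is off. With mediation on, the
mediated exposure's total variance exceeds its nominal target (the
structural coefficients, which are the estimands, are unaffected); with
the default α_CA = 0.5 the realised education SD is ≈ 2.48.

The structural binary outcome is smoking initiation, generated by a
linear-probability mechanism so that risk differences are the estimands:

    P(ever = 1) = b₀ + β₁(E−μ_E) + β₂C + c_S·U + G·δ + d·E_parent

with b₀ = 0.438, per-SNP direct (pleiotropic) effects δⱼ ~ N(mean, sd)
on centred dosages (mean ≠ 0 encodes directional pleiotropy), and an
optional dynastic term. Probabilities are clamped to [0,1]; clamping
beyond 1% of the cohort triggers a warning because it attenuates the
generated risk differences at the boundaries. At the default paper-scale
β₁ = −0.09 about 2.5% of probabilities clamp; at the |β₁| ≤ 0.04 used in
the recovery experiments clamping is negligible.

Cessation among ever-smokers has its own linear mechanism with
coefficients (+0.053 per year, −0.051 per SD) matching the scale of the
direct cessation effects the individual-level design targets, and
`smoke_current = ever AND NOT former`. Because ever-smokers are selected
towards low education and low cessation probability, the cessation
intercept (0.885) sits above the target former-among-ever share; the
realised shares reproduce the emulation targets 7.7% current / 43.8%
ever / 82.4% former-among-ever.

Dynastic variant: maternal and paternal genotypes are drawn explicitly
and one allele per parent is transmitted (Binomial(1, dosage/2)), so the
offspring marginal distribution is unchanged; parental education is the
parents' mean score-plus-noise value and enters the offspring outcome
directly — the classic violation of instrument independence that
within-family designs remove.

Selection: participation is logistic in centred education and current
smoking; `apply_selection` returns the participation probabilities so
re-weighting can be validated against truth. Genetic "PCs" in the
covariates are pure noise columns — population structure is explicitly
not simulated.

All randomness flows from one root seed through named
`numpy.random.SeedSequence` spawns, so identical parameters give
bit-identical output.

### Two-sample summary data

`simulate_two_sample_summary` draws three *independent* cohorts sharing
one instrument panel (education GWAS, cognition GWAS, outcome GWAS — no
sample overlap), then computes per-SNP simple-regression associations
(vectorised closed form; per-SNP logistic IRLS for the log-odds scale).
Monomorphic SNPs are excluded with a log entry.

A caveat that matters for interpretation: with cohort-scale GWAS sizes
(tens of thousands) the *per-SNP* instrument strength is weak
(F ≈ n·r²/m per SNP), and two-sample IVW then suffers regression
dilution towards the null — visible as ~20–30% shrinkage in the summary
example. Real exposure GWAS for these traits have n ~ 10⁵–10⁶ and
genome-wide-significant instruments, where the dilution is a few
percent. The quantitative summary-level recovery experiments therefore
use `sample_summary_from_truth`, which draws the summary statistics
directly from their sampling model at realistic per-SNP precision
(se_π = 0.002 against effects of magnitude ~0.05, per-SNP F ≈ 600);
this is also the regime in which the χ² calibration of the modified Q
is exact by construction, making it the right null for calibration
tests. The cohort-based summary generator remains the end-to-end
integration route and is validated qualitatively (Wald-ratio
consistency, SE ∝ 1/√n, test size).

## Estimators

**OLS** (`ols_estimate`): weighted linear-probability regression on both
exposures plus the covariate block, HC1 robust SEs (LPM errors are
intrinsically heteroskedastic).

**2SLS** (`tsls_univariable`, `tsls_multivariable`): regressors
X = [1, W, exposures], instruments Z = [1, W, scores]; β̂ = (X̂'X̂)⁻¹X̂'y
with X̂ the projection of X on Z. The covariance is the proper IV
sandwich — structural residuals y − Xβ̂ over the projected design, HC1
scaled — not the naive second-stage OLS formula, which ignores
first-stage estimation. The conditioning check for a (near-)singular
projected design is done on the scale-equilibrated cross-product so raw
covariate units (calendar years) cannot masquerade as collinearity.
Score collinearity above |r| = 0.999 is an error; first-stage or
conditional F below 10 is a warning.

**Conditional F** (`conditional_f`): for target exposure x_t, the other
exposures are instrumented out by 2SLS, the structural residual is
regressed on all instruments and covariates, and the joint instrument
Wald statistic is referred to kz − kx + 1 numerator degrees of freedom
(implemented as the standard F times kz/(kz − kx + 1)). The scaling is
pinned by two properties verified in tests: with a single exposure the
statistic equals the first-stage F exactly, and with orthogonal
single-purpose scores it approaches the exposure's own-instrument F.
Note the multivariable `f_stat` reported alongside it is the *joint* F
of both scores; the conditional F can exceed it when the scores are
nearly orthogonal, and collapses below it as they become collinear.

**IVW / MVMR-IVW** (`ivw_univariable`, `mvmr_ivw`): weighted least
squares of Γ̂ on the exposure associations through the origin with
first-order weights 1/se(Γ̂)². Fixed-effect SEs from (X'WX)⁻¹; a
multiplicative overdispersion option is deliberately not enabled by
default so the estimator matches the plain regression form.

**MR-Egger** (`mr_egger`): the same regression with a free intercept,
after orienting SNPs so the first-listed exposure association is
non-negative (the intercept is not invariant to allele-coding sign
flips; orientation is stated because the multivariable convention is not
unique). The intercept estimates mean directional pleiotropy per SNP
under InSIDE.

**Modified Q** (`modified_q`): per-SNP contribution
qⱼ = wⱼ(Γ̂ⱼ − Σβ̂π̂ⱼ)² with wⱼ = 1/(se_Γⱼ² + Σβ̂²·se_πⱼ²), which
propagates the exposure-side uncertainty. When no coefficients are
supplied they are estimated by iterating WLS with these exact weights to
convergence (tolerance 1e-10). Q_total is referred to χ² on
L − (#exposures) df, each qⱼ to χ²₁. The weight form is validated by
calibration: under the no-pleiotropy null with L = 100 the mean is ≈ 98
and the 5% test rejects at ≈ 5%. Outlier handling
(`remove_outliers_and_refit`) is one-shot — flag at per-SNP p < α,
remove, refit once — not iterated.

**Presentation**: `sd_scale` converts per-unit risk differences to
per-SD and percentage form (half-up rounding to 1 dp, e.g. −0.026 per
year × 2.4 years/SD → −0.0624 → 6.2%); `to_odds_ratio` exponentiates
log-odds effects.

## Phenotype and score construction

The qualification→years map (6 categories, years ∈ {15,16,18,20,21}) is
shipped as a package data file; "None" is a category label, which is why
the reader disables NA-parsing. Score standardisation uses the sample SD
(ddof = 1) and rejects constant input. Smoking derivation enforces
current ⇒ ever and defines cessation only among ever-smokers, reporting
counts and half-up percentages. The covariate block is age, sex, year of
birth, sex×year-of-birth and the first n PCs; n_pcs defaults to 10,
configurable (analyses of this design have used 10 or 40). Rank is
checked incrementally so the first collinear column is named.

Harmonisation aligns a weight panel to a target allele coding: swapped
alleles flip the weight sign (equivalently dosage → 2−d), complementary
coding is resolved by strand, palindromic A/T and C/G SNPs are dropped
by default (their strand cannot be resolved without frequencies;
`palindromic="keep"` overrides), incompatible pairs are dropped, and
losing more than 20% of the panel is an error. LD pruning is greedy at
pairwise r² ≤ threshold in ascending p-value order with lexicographic
tie-breaks — deterministic, and checked against an independent
brute-force implementation.

## Validation experiment design (problem sizes)

- Parameter recovery: 200 replicates at n = 20,000, (β₁, β₂) =
  (−0.04, 0) with α_E = 0.5 or α_CA = 0.5; multivariable means within
  2 Monte-Carlo SEs of the direct effects, univariable means within
  2 MC SEs of the composite totals β₁ + α_E β₂ and β₂ + α_CA β₁.
- Attenuation signature: 100 replicates at n = 50,000 under the default
  (α_CA) DAG at paper-scale β₁ = −0.09; a replicate counts when the
  univariable cognition estimate has the sign of its total effect and
  the multivariable estimate moves from it toward zero.
- Calibration: 500 replicates for Q (L = 100) and the Egger intercept
  coverage (L = 50); 400 replicates for the empirical size of the power
  estimator at n = 5,000 with r² = 0.02 instruments (size is assessed at
  strong first stage because weak-instrument IV t-tests are
  conservative, which is itself visible in the generator at small n).

These sizes keep the full suite and the acceptance script to a few
minutes on one CPU while leaving each check powered against its own
Monte-Carlo noise.

## Known limitations

- The linear-probability outcome clamps at paper-scale effect sizes
  (~2.5% of individuals at β₁ = −0.09), mildly attenuating generated
  risk differences; a logistic outcome track is provided for the
  odds-ratio analyses.
- No LD is generated between SNPs (pruning operates on user-supplied
  correlation matrices); no population structure, no imputation, no
  within-family estimators.
- Two-sample summary estimates from cohort-scale simulated GWAS carry
  weak-instrument dilution (see above) — a property of the regime, not
  of the estimator.
- One-shot outlier removal can discard legitimate SNPs (~α·L under the
  null) and is not robust when contamination is strong enough to drag
  the initial fit; this mirrors the procedure it implements.
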