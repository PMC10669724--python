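# Methods

This note documents the statistical procedures implemented in `gxecross`,
the conventions chosen where several are defensible, what the synthetic
cohort generator does and does not emulate, and the package's known limits.

## 1. Cohort handling

A cohort is one row per child: gender (1 = male, 2 = female), age in years,
three ordinal SES codes (parental education 1–6, parental occupation 1–10,
monthly income 1–5), a home-supervision exposure (five 1–5 items and/or
their composite), a reading-achievement outcome, and string genotype calls
per SNP.  Out-of-range codes and non-positive ages become missing at read
time with a warning count; nothing is ever zero-filled.

**Standardization.** Z scores use the sample SD (denominator n − 1)
throughout, for both standardization and variance computations.  Gender and
age are left on their raw scales in regressions (standardized coefficients
are still comparable because β = b·SD(x)/SD(y) is reported for every term).
Interaction terms are products of the already-standardized components and
are *not* re-standardized; their β uses the product's own SD.

**Reliability.** Cronbach's α = k/(k−1) · (1 − Σ item variances / total
variance) on listwise-complete item rows.

**Missing data.** EM under a multivariate normal model: the E-step computes
each row's conditional means and second moments of its missing entries given
the observed ones at the current (μ, Σ); the M-step re-estimates μ and Σ by
maximum likelihood (denominator n).  Convergence is declared when the
observed-data log-likelihood changes by less than a relative 1e-6 (cap 500
iterations); the trace is exposed and is monotone non-decreasing, which the
tests assert.  A near-singular Σ receives a ridge of 1e-8·trace(Σ)/p.
After convergence, missing cells are replaced by their conditional means —
single imputation, chosen because the downstream analyses treat the
completed table as fixed.  Conditional-mean imputation shrinks the imputed
variable's spread; analyses that need unbiased second moments should use the
EM-estimated Σ, not the completed table's sample covariance.

**Correlations.** Pearson r with two-sided p from t = r√((n−2)/(1−r²)),
pairwise-complete by default with a listwise option (the descriptive table
convention of the motivating study is not stated, so neither mode is claimed
as "the" published one).

## 2. Genotype QC

Call rate, allele frequencies from genotype counts (p + q = 1 by
construction), MAF = min(p, q), and Hardy–Weinberg equilibrium by the 1-df
chi-square on observed vs expected genotype counts (no continuity
correction), with an exact test (conditional distribution of the
heterozygote count given allele counts) available for rare-genotype
situations where the chi-square approximation is unreliable.  Default
thresholds: call rate ≥ 0.95, MAF > 0.05, HWE p > 0.01.  QC failures are
*reported, never dropped*: the motivating cohort retains a SNP with
MAF ≈ 0.022, and a locus observed without its minor homozygote necessarily
fails HWE, so filtering is left to the analyst via an explicit include-list.
Two-level codings (e.g. GT = 0 / TT = 1) are treated as two-group factors
downstream; the additive −1/0/1 coding is used where three genotypes are
observed.

## 3. Exploratory stage

**Hierarchical OLS.** Blocks enter in order (covariates → main effects →
products); for block k, ΔF = (ΔR²/Δk) / ((1 − R²_k)/df2_k) with p from the
F distribution — the increment test using the current block's residual
variance, whose single-term special case equals the added term's squared t.
All blocks are fitted on the listwise-complete rows of the final block so
increments are computed on identical data.

**Simple slopes.** slope(z) = b_X + b_XZ·z with variance
V_XX + 2z·V_X,XZ + z²·V_XZ,XZ on the fit's residual df.

**Johnson–Neyman regions of significance.** The genotype-group difference
at environment X is θ(X) = b_Z + b_XZ·X; boundaries solve
(b_XZ² − t²V_pp)X² + 2(b_Z·b_XZ − t²V_zp)X + (b_Z² − t²V_zz) = 0 at
t = t(1 − α/2, df2), handling 0/1/2 real roots.  Both the recommended
mean ± 2 SD window and the observed min/max are reported.

**PoI and PA.** With straight lines crossing at C, the between-line area on
each side of C is proportional to the squared distance to the range end, so
PoI = (hi − C)²/((hi − C)² + (C − lo)²) when the risk group has the steeper
slope (the orientation flips otherwise).  *Range convention:* the default is
the observed min/max of X — the only convention consistent with the
motivating study's printed trio (C = 0.49, range −4.31…1.85 → PoI ≈ 0.07);
the mean ± 2 SD convention that the same methodology text recommends is
available as an option.  PA is the share of observed X strictly beyond C by
default, with an analytic standard-normal tail option for when raw values
are unavailable (a Z-scored environment makes the normal tail the natural
reconstruction).

**Nonlinearity probe.** The interaction model is refitted with X² and Z·X²
added; their p-values, and the X·Z p-value before and after augmentation,
are reported.  A "G×E" that disappears here was likely curvature in X
masquerading as moderation.

**Multiplicity.** Holm's step-down (sequential Bonferroni): the i-th
smallest of m p-values is compared with α/(m − i + 1), stopping at the first
non-rejection.  Rejections are therefore a superset of Bonferroni's and a
subset of uncorrected testing's, which the property tests assert.

## 4. Confirmatory stage: crossover regression

Model and variants as in the README.  Estimation is closed-form for every
variant:

- fixed C (models c–f): ordinary least squares on
  (1, D₁(X − C), D₂(X − C), covariates), with C recomputed per dataset as
  the observed extreme of standardized X;
- model b: OLS on (1, D₂, X, D₂X, covariates) mapped through
  C = −γ_D2/γ_D2X, B1 = γ_X, B3 = γ_X + γ_D2X, B0 = γ_0 + B1·C;
- model a: OLS on (1, D₂, D₂X, covariates) mapped through B0 = γ_0,
  B3 = γ_D2X, C = −γ_D2/γ_D2X (the model is linear because
  B0 + B3·D₂·(X − C) = B0 + B3·D₂·X − (B3C)·D₂).

Since the free-C variants are exact re-parameterizations of linear models,
no iterative optimization is needed; a nonlinear-least-squares oracle in the
test suite confirms the closed form attains the optimum.  Standard errors of
the nonlinearly mapped parameters (C, and B0 in model b) use the delta
method on the OLS coefficient covariance; the 95% CI for a free C is
C ± t(0.975, n − k)·SE.  The delta-method SE is accurate when the crossover
is well identified (slope contrast large relative to its SE); under weak
identification the sampling distribution of the ratio C is heavy-tailed and
no symmetric CI is trustworthy — `fit_reparam` raises an unidentified-
crossover error only at a numerically zero slope difference, so users should
read the CI width critically.

**Degrees of freedom.** The overall model F uses df1 = number of slope
terms (intercept and C not counted) and df2 = n − 1 − df1, matching the
printed convention of the motivating study (model b reported as F(7, 737)
at n = 745).  Nested F-tests count *every* released constraint including C:
F = ((SSE_r − SSE_f)/Δdf)/(SSE_f/(n − k_f)) with k_f counting all free
parameters of the nesting model (9 for model b).

**AIC/BIC.** AIC = n·ln(SSE/n) + 2k, BIC = n·ln(SSE/n) + k·ln n.  Two
parameter-count conventions coexist deliberately.  The *printed* per-model
AIC/BIC use k = free mean parameters excluding a free C — back-computation
from the motivating study's comparison table shows that is the convention
its values follow.  The *selection* rule, however, counts a free C: under
the printed convention a free-C model receives a 2-point AIC subsidy
relative to a fixed-C model with the same number of slope parameters,
rewarding a parameter that was in fact fitted.  `information_criteria`
exposes both via `count_crossover`.

**Selection.** Each alternative (a, c, d, e, f) is screened by its F-test
against b at α = 0.05 and rejected if significantly worse.  If all fall,
b stands.  Among surviving alternatives the default picks the lowest AIC
(C counted; ties → BIC → fewest parameters).  A parsimony-first rule (fewest
free parameters among survivors) is available but not default: the F screen
against b has low power for small slope effects (the 2-df tests of the
strong models especially), so a wrongly-constrained but more parsimonious
model frequently survives, and parsimony-first would hand it the verdict;
the AIC comparison weighs the surviving models' actual fit.  Risk-group
assignment (which genotype carries slope B3) is configuration, defaulting to
GT at rs11629841.

## 5. Synthetic cohort generator

The generator emulates the motivating cohort's structure so every stage has
ground truth:

- n = 745; genotype calls multinomial at the observed frequencies
  (rs3743205 33/712, rs11629841 155/590, rs8040756 539/189/17 per 745);
- gender, age, the three ordinals and the home-supervision latent drawn from
  a Gaussian copula whose latent correlations are the study's rounded
  descriptive values (e.g. education–income −0.36, supervision–education
  0.11); ordinals discretized to their ranges by quantile thresholds, age
  scaled to mean 9.78, SD 0.69;
- five scale items share the supervision latent with inter-item latent
  correlation 0.40, which lands Cronbach's α near the instrument's 0.75
  after 5-category discretization;
- the outcome follows the crossover model with defaults from the study's
  accepted weak diathesis–stress fit: B1 = 0.10, B3 = 0.21, B4…B8 =
  (0.08, −0.52, 0.10, 0.14, 0.01), C at the sample maximum of standardized
  supervision (minimum for vantage truths, 0.49 for free-crossover truths);
- residual SD 0.91, derived so the full-model R² matches the study's 0.214:
  the systematic part contributes ≈ 0.23 outcome variance (age ≈ 0.13,
  occupation 0.14², education 0.10², environment slopes and the
  between-group shift ≈ 0.05), and 0.23·(1 − 0.214)/0.214 gives σ² ≈ 0.83.
  Measured R² under the defaults is 0.216.

What it does *not* emulate: the real environment distribution (the study's
standardized supervision ranged −4.31…1.85, i.e. left-skewed with a ceiling;
the generator draws a symmetric normal, so its sample extremes sit near
±2.8–3.2 and fixed-C leverage differs from the study's), linkage
disequilibrium between SNPs, MNAR missingness, and measurement error linking
the item scale to the exposure actually driving the outcome (the composite,
not the noisy items, generates Y).  Consequently, passing tests demonstrate
the *method's* correctness and calibration under a faithful-by-construction
cohort, not that the study's printed coefficient table would be reproduced
from its raw data.

A consequence worth stating plainly: with slope contrast B3 − B1 = 0.11,
groups of 155/590 and σ = 0.91, the interaction's sampling SE is ≈ 0.08, so
the simulated interaction averages |t| ≈ 1.3 and reaches p < 0.05 in only
about a fifth of cohorts.  The motivating study's observed interaction
(t = 2.85) corresponds to its *unconstrained* slope-contrast estimate
(0.24), not the constrained weak-diathesis–stress values used as generating
truth here.  Simulation-based checks therefore assert direction and
calibration (sign recovery, CI coverage, selection frequency) rather than
per-cohort significance.

## 6. Numerical conventions

- OLS via the normal equations with an explicit rank check; collinearity is
  an error naming the terms, not a silent drop.
- Crossover undefined when |slope difference| < 1e-10 (error, not ±∞).
- A crossover outside the PoI range is clamped to the nearer end
  (PoI 0 or 1).
- Perfect fits (noiseless data) report F = ∞ and omit information criteria.
- α = 0.05 two-tailed everywhere unless configured; significance stars at
  0.05/0.01/0.001.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds reproduce cohorts, reports and
  JSON byte-for-byte.

## 7. Pipeline

`run_pipeline` chains load/simulate → genotype coding + QC → EM imputation
(skipped when nothing is missing) → standardization → correlations →
hierarchical regression → RoS diagnostics → six-model comparison →
selection, writing `report.json`, `report.md` and CSV tables.  Any stage
failure aborts with the stage name and the completed sections attached.
The CLI (`gxecross simulate|qc|regress|ros|reparam|run`) is a thin wrapper
over these calls.

## 8. Limitations

- Two genotype groups per crossover fit (the methodology dichotomizes);
  three-genotype additive codings enter the exploratory stage only.
- Single imputation (see §1); no MICE/multiple imputation.
- No robust/clustered standard errors, no latent-variable measurement model
  for the exposure, no confirmatory factor analysis of the scale.
- The delta-method CI for C degrades under weak identification (§4).
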