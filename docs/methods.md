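# Methods

This note documents the statistical procedures, the synthetic-cohort model
and the numerical choices behind `elastoconcord`.

## Standardization of elasticity

Device ranges differ (2D-SWE reads up to 300 kPa, transient elastography up
to 75 kPa) and kPa distributions are strongly right-skewed, so raw
stiffness is not comparable with blood-test scores on [0, 1]. The default
transform clamps to [1, 75] kPa, takes log10 and rescales:
`s(E) = log10(clamp(E, 1, 75)) / log10(75)`. Two variants are kept as
sensitivity switches: `LINEAR_74` (`(clamp(E,1,75) − 1)/74`, the purely
linear rescaling over the same range) and `LOG_ONLY` (unscaled log10). The
sources describing this design are ambiguous about whether the division by
the range happens before or after the log transform; both readings are
implemented and the log-range form is the default because it is the
distribution used downstream. All variants are monotone, so rank-based
quantities are unaffected; the CCC is not, which is the point — an
unstandardized device with a larger range suffers an artificial concordance
penalty, and the package reproduces that on simulation.

The per-patient statistic fed downstream is the mean of the region-of-
interest (Qbox) stiffness values by default, configurable to the median.

## Lin concordance correlation coefficient

For paired vectors x, y the estimate uses n-divisor moments
(`CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`, Lin's original estimator; the
n−1 variant differs at O(1/n) and is indistinguishable at cohort sizes).
The bilateral 95% interval applies the Fisher z-transform with Lin's
asymptotic variance

    var(ẑ) = 1/(n−2) · [ (1−r²)ρ̂² / ((1−ρ̂²)r²)
                        + 4ρ̂³(1−ρ̂)u² / (r(1−ρ̂²)²)
                        − 2ρ̂⁴u⁴ / (r²(1−ρ̂²)²) ],

with r the Pearson correlation and u = (x̄−ȳ)/√(sₓs_y). Coverage is
validated at 93–97% over 1,000 bivariate-normal replicates (n = 200) in the
acceptance suite. Degenerate cases: both inputs constant with equal means
is undefined and raised; |ρ̂| = 1 or a zero-variance input returns a
point-mass interval.

Dependent CCCs (two devices against one reference on the same patients)
are compared by a seeded paired bootstrap over patients (default 2,000
replicates, percentile interval, two-sided tail p-value), since no closed
form for the dependent case is in common use. A seed is mandatory.

## Reliability screening by strength of concordance

With two *imperfect* references, a factor that genuinely destroys one
test's reliability should annihilate its concordance with an independent
reference in the affected subgroup only. The screen bins the 2D-SWE
reliability population by a candidate criterion (minimal Qbox elasticity
with edges 0.2/0.5/1.0 kPa; shot CV; depth; WHO BMI classes), computes the
CCC of standardized 2D-SWE elasticity against each reference per bin
(half-open bins [lo, hi), so the 0.2 kPa boundary itself is reliable), and
flags bins whose interval with the primary reference contains zero. The
verbal rule "significant concordance in some bins but not others" is
formalized as: *discriminant ⇔ at least one tested bin flagged and at
least one not*. Bins with fewer than 10 complete pairs are excluded with a
notice. "Significant" is read as the 95% CI excluding zero rather than a
p-value on the CCC; the two are equivalent under the Fisher-z interval.

## Applicability

Each patient gets exactly one status per test: FAILURE (no signal/sample),
NOT_RELIABLE (quality rule violated: TE IQR/M ≥ 0.30, < 10 valid shots or
success rate < 60%; 2D-SWE minimal signal < 0.2 kPa; FibroTest an internal
reliability flag — the component-level rule needs serum components that are
proprietary and not modelled), else APPLICABLE. Rates carry Wilson score
intervals; the published bounds are reproduced exactly except one upper
bound that appears to be a publication rounding artefact. Rate comparisons
use the pooled two-proportion z-test, which reproduces the published
statistics despite the paired design; a McNemar option is provided.
Percents are rounded half away from zero to one decimal.

## Curve fitting

The elasticity–score relation is fitted by OLS and by a continuous
three-part piecewise-linear model via the truncated power basis
{1, x, (x−b₁)₊, (x−b₂)₊}. Continuity at the breakpoints is enforced
(the alternative, disconnected pieces, is not identifiable from the
published figures and continuous curves are the natural reading).
Breakpoint pairs are grid-searched exhaustively over 40 quantile-spaced
candidates between the 5th and 95th percentile of x, requiring at least 4
points per segment, minimizing SSE with ties broken toward the smaller
first breakpoint (strict-improvement iteration in grid order, so the
search is deterministic). R² differences between devices are assessed by a
paired bootstrap that keeps each fit's breakpoints fixed and refits only
the segment coefficients per replicate — breakpoint re-search per replicate
would cost O(grid²) least-squares solves and its uncertainty is
second-order for an R² difference.

## Diagnostic performance

The endpoint is severe fibrosis (F3F4) presumed by FibroTest at a
configurable cutoff. The AUROC is the Mann–Whitney statistic with midrank
ties (rank-sum form, so it equals brute-force pair counting exactly);
variance and the paired device comparison use DeLong placement values, the
covariance method for correlated ROC curves. Logistic adjustment models
(elasticity + activity + steatosis + NAFLD/CHC indicators) are binomial
GLMs fitted by IRLS through statsmodels; perfect separation is flagged as
non-converged rather than raised. Multivariate AUROCs are in-sample (no
cross-validation is described for the design being emulated).

Intention-to-diagnose analyses retain non-applicable patients with the
worst-case standardized value 1 − FibroTest; per-protocol analyses use
applicable measurements only. Presumed-prevalence combinations classify
patients at a raw-kPa cutoff (default 9.5 kPa, the same for all three
devices) either per device, by the worst of the three values, or among
patients whose three classifications agree.

### Assumed cutoffs

The blood-test dichotomies are cited to the tests' manuals but not printed
in the design source; they are config values with documented defaults:
ActiTest A2A3 ≥ 0.52, SteatoTest S2S3S4 ≥ 0.57, FibroTest F3F4 ≥ 0.58.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
known truth for recovery testing. Per patient (single seeded
`default_rng` stream, draws in documented order):

* **Latents.** Disease ∈ {CHC, CHB, NAFLD, ALD, OTHER} with the
  concordance-population mix (0.377/0.230/0.254/0.047/0.092); METAVIR
  stage F0–F4 with probabilities (0.25, 0.25, 0.254, 0.15, 0.096);
  activity grade A0–A3 ~ Binomial(3, 0.20 + 0.15·max(0, stage−2)) — flat
  below F3 so stage confounding does not masquerade as an inflammation
  effect within the F0F1F2 stratum; steatosis S0–S4 ~ Binomial(4, p) with
  p raised for NAFLD (+0.28) and ALD (+0.10).
* **Blood scores.** Monotone grade→score maps plus truncated Gaussian
  noise (sd 0.08), clipped to [0, 1]. Patients with a test interval over
  30 days (3.3%) get 3× noise — the planted interval effect. SteatoTest is
  missing in 20% of patients; FibroTest carries a 0.53% not-reliable flag.
* **Stiffness.** True stiffness =
  base(stage) × (1 + (a·AT + b·ST)·g(stage)) × lognormal(σ = 0.20), with
  base = (4.5, 5.5, 7.0, 9.5, 14.0) kPa, g(stage) = 0.5 + 0.35·stage
  (inflamed or fatty tissue stiffens more when fibrotic), and
  device-specific inflation a = 0.40/1.20/0.75, b = 0.35/0.65/0.25 for
  2D-SWE/TE-M/TE-XL. The coefficients are calibrated to reproduce the
  orderings the analyses should recover (TE-M more inflated than 2D-SWE;
  impact larger in F3F4), not any published magnitude, which is not
  identifiable.
* **Sessions.** 10–15 shots per device around the true stiffness
  (lognormal σ = 0.12), from which mean/median/min/max, CV and IQR are
  computed organically, so the reliability rules act on real summaries.
  TE sessions are occasionally noisy (σ = 0.55 ⇒ IQR/M ≥ 0.30) or short
  (< 10 valid shots); TE failure probability is logistic in BMI for the M
  probe (mean ≈ 8%) and constant for XL (2.8%); 2D-SWE fails in 0.9%.
* **Qbox minimum.** The reported 2D-SWE minimum is the session minimum
  combined with a lognormal pixel-minimum tail (μ = −2, σ = 1 on the log
  factor) floored at 0.22 kPa: reliable maps populate the 0.2–0.5, 0.5–1
  and ≥ 1 kPa bins across all stages, and values below 0.2 kPa arise
  *only* from the dead-signal mechanism — 7.7% of patients whose map
  minimum is Uniform[0, 0.2) and whose stiffness is re-drawn independently
  of stage.

What the generator does **not** emulate: serum-component algorithms (blood
scores come from latent grades directly), biopsy error, operator and
machine drift, correlated multi-visit structure, ascites and other
anatomical failure causes beyond the BMI link, or any real joint
distribution of the published cohort. Passing recovery tests therefore
shows the *estimators and decision rules* behave correctly under the
assumed structure; it does not validate the clinical findings on real
patients.

## Problem sizes and determinism

Recovery tests run at the cohort sizes the analyses target (1,200–2,251
patients); the screening power/false-positive criterion uses 100 seeded
cohorts of 1,700, and interval coverage 1,000 replicates of 200. All
bootstraps and simulations require explicit seeds; identical config + seed
gives byte-identical pipeline outputs. Percent rounding is half away from
zero to one decimal throughout the report tables, with full-precision
companions.

## Known limitations

* The Fisher-z CCC interval is asymptotic; below n ≈ 30 the paired
  bootstrap comparison flags a warning instead of pretending precision.
* The dependent-CCC and R² comparisons are bootstrap-based; their p-values
  inherit Monte-Carlo granularity of 1/n_boot.
* Worst-case intention-to-diagnose imputation (1 − FibroTest) against a
  FibroTest-defined endpoint is deliberately pessimistic and circular by
  construction; it bounds, not estimates, the missing-data impact.
* The three-part fit's breakpoint grid is quantile-spaced; breakpoints are
  only identified up to grid resolution (tested at that tolerance).
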