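# Methods

This note records the models behind each module, the parameters that
matter, the numerical choices, and what validation on synthetic data does
and does not establish.

## Data-generating model

The synthetic cohort is governed by `SimConfig`. The defaults describe
the study conditions the estimators are validated under; they are fixed,
not tuned per analysis.

**Genotypes.** Dosages in {0,1,2} arise from two latent-Gaussian
haplotypes thresholded at the allele-frequency quantile, with MAFs drawn
uniformly from `maf_range` (default 0.05–0.5). LD is block-structured:
within a block of `ld_block_size` variants (default 10) the latent
correlation decays as AR(1) with adjacent correlation `within_block_r`,
and the block strength cycles over {1, ⅔, ⅓, 0}·`within_block_r` from
block to block. The AR(1) decay and the block-to-block cycling are
deliberate: a genome whose variants all tag the same amount of variation
gives LD score regression nothing to regress on — the slope (h²) and
intercept become collinear. Thresholding attenuates the latent
correlation (a latent 0.8 becomes a dosage r around 0.5), so realised LD
scores with the default geometry span roughly 1–2.5.

**Traits.** Per-variant exposure effects are N(0, h²/m_causal) on
standardized dosages (the standard polygenic model, matching the LDSC
assumptions), plus a confounder term and Gaussian noise; the exposure is
z-scored. The binary fall indicator follows a logistic model —
logit P(fall) = c + θ·exposure + γy·U + age and sex terms — with the
intercept c tuned by root-finding so the realised case fraction matches
`case_prevalence` (default 0.10, the prevalence regime of a
records-derived fall phenotype in a population cohort). The binary
outcome lives on the log-odds scale throughout because every estimator
applied to it (Firth logistic scan, logistic second stages) works on
log-odds; no liability-scale machinery is used (an observed-to-liability
h² transform is provided separately and requires a user-supplied
population prevalence).

**Fall counts.** Cases receive 1 + Poisson(λᵢ) falls with
log λᵢ sharing the causal linear predictor and the mean extra-fall rate
set by `count_mean_extra` (default 0.37, which puts ~31% of cases above
one fall — the observed fraction in records-derived fall counts). The
1+Poisson form guarantees case ⇔ count ≥ 1 with simple moments. Real
fall counts are over-dispersed to an unknown degree; a gamma-frailty knob
(`count_dispersion`) is exposed but defaults to 0 rather than pretending
to a calibration the data do not support.

**Event logs.** Each case's falls become distinct ISO-8601 dates (HES
window 1995–2021, GP window 1955–2017), each date carrying 1–3 distinct
balance-fall codes so the same-date deduplication rule is exercised;
everyone also receives unrelated records except a small flagged
"no-records" subset of controls that exercises the exclusion rule. No
calendar realism beyond ordering is attempted, and the bundled code list
is a synthetic stand-in with the right structure (ICD-10 W-chapter-like
and Read-like codes in three categories), not a clinically reviewed list.

**Summary-statistic pairs.** For the two-sample and overlap analyses,
per-variant exposure effects are drawn with variance h²ℓⱼ/m (ℓⱼ an
emulated LD score, uniform 1–4, returned as truth), outcome effects are
θ·βx plus a pleiotropy term (none / balanced / directional), and the two
tables' estimation errors are bivariate normal with correlation
ρ = `overlap_fraction` × (γx γy + θ) — overlap is induced at the
estimation-error level rather than by resampling shared individuals,
matching the summary-statistics abstraction the overlap correction works
at. An optional selection step retains variants with estimated exposure
p < `selection_pvalue`, which reproduces winner's curse.

**What passing tests show.** Recovery and calibration on this generator
establish the estimators' algebra and their behaviour under the stated
causal structure. The generator has no population stratification,
relatedness, imputation error beyond an INFO label, assortative mating,
or realistic human LD; conclusions about robustness to those features do
not follow.

## Estimators and numerical choices

**Firth scan.** Newton iterations on the modified score
X'(y − p + h(½ − p)), tolerance 1e-8 on the score norm, 50 iterations
maximum, step-halving on penalised-likelihood decrease. The LRT null is
the *constrained* penalised fit (variant coefficient pinned at zero, the
Jeffreys penalty still computed on the full design); using a
reduced-design fit instead would shift the statistic by the
log-determinant dimension change and destroy calibration. SEs come from
the inverse penalised information. Whole-genome ridge/LOCO machinery is
deliberately absent: desk-scale synthetic cohorts have no relatedness or
structure to absorb, so plain covariate adjustment is the appropriate
scan.

**LDSC.** Scores use the small-sample adjustment r²−(1−r²)/(n−2) over a
symmetric window (window ≥ block size covers all real LD).
Heteroskedasticity weights 1/(max(ℓ,1)·(1+N h² ℓ/M)²) are updated once
(two-step). Jackknife uses 20 contiguous blocks. For rg, the cross
regression weights are the geometric mean of the two traits' h² weights,
which makes rg(trait, itself) exactly 1 and rg symmetric in its
arguments; p-values are normal-theory on the jackknife SE. h² is
reported on the observed scale only.

**Two-sample MR.** IVW defaults to multiplicative random effects
(SE × max(1, √(Q/(k−1)))) — robust under the heterogeneity such analyses
usually show — with fixed effects available; k = 1 degrades to the ratio
estimate and is labelled as such rather than silently substituted.
MR-Egger re-orients instruments so all βx ≥ 0 (the intercept is
orientation-dependent; a fixed convention makes results reproducible) and
uses the *untruncated* residual scale √(Q/(k−2)) with t(k−2) inference,
which makes the pleiotropy (intercept) test exactly calibrated under the
null — truncating the scale at 1 would push its type-I error to ~2%.
Weighted-median uncertainty is a seeded parametric bootstrap (default
1,000 draws) rather than the analytic approximation, because it is
directly verifiable by simulation. The PWM penalty multiplies each weight
by min(1, qⱼ/α) with qⱼ the χ²₁ upper-tail probability of the
instrument's heterogeneity contribution about the WM estimate and
α = 0.05 (equivalently the familiar 20·qⱼ form); α → 0 recovers the
plain WM. Palindromic ambiguity uses the conventional EAF window
0.42–0.58.

**One-sample MR.** The allele score is Σⱼ wⱼ·dosageᵢⱼ with missing
dosages mean-imputed to 2·EAF (preserves the score expectation);
multi-instrument first stages are supported but the score is the default,
as is conventional when only aggregate weights are published.
Second-stage SEs are HC0 sandwich with the first-stage fit treated as
fixed — the usual practice for 2SLS with binary outcomes; the neglected
generated-regressor term is small at the instrument strengths (F > 30)
these analyses require, and coverage at those strengths is verified by
simulation. Stratified analyses refit the first stage within each
stratum, because a stratum-specific instrument–exposure relation is the
premise of the never/ever negative control. Sex-specific selection tests
the interaction z = (βm−βf)/√(se²m+se²f) at `interaction_alpha`
(default 1e-5 — only the F threshold, 15, strict, is a fixed convention;
the interaction criterion is a package choice) and assigns each hit to
the sex with the larger |β|/se.

**Overlap-corrected IVW.** Three biases are removed through the
polygenic structure estimated from the same summary data. With
τ²ⱼ = h²ℓⱼ/M the prior variance of variant j's marginal effect, the
conditional expectation of the true effect given its estimate is the
shrinkage μⱼ = β̂xⱼ τ²ⱼ/(τ²ⱼ+se²xⱼ); because significance selection is a
function of the observed estimate alone, this posterior mean remains
valid for the selected instruments, which is what neutralises winner's
curse. The corrected estimator is

θ̂ = Σ wⱼ[β̂xⱼβ̂yⱼ − ρ(se_yⱼ/se_xⱼ)β̂xⱼ(β̂xⱼ−μⱼ)] / Σ wⱼ μⱼ β̂xⱼ,

with ρ the cross-trait LDSC intercept: the denominator removes
regression dilution (it reduces to β̂x²−se²x without selection) and the
subtracted term removes the overlap covariance. The h² entering the
prior is floored by a method-of-moments slope with the intercept pinned
at 1 — the free-intercept LDSC h² can collapse to ~0 on short tables,
which would zero the prior and blow up the corrected denominator. A
prior-free per-instrument truncated-normal deconvolution is provided as
a diagnostic (`winners_curse_deconvolve`); it is not used in the
estimator because it over-corrects for instruments sitting near the
selection threshold. The observed-vs-corrected difference test combines
a leave-one-instrument-out jackknife (the two estimates are strongly
dependent, so naive variance addition is wrong) with the propagated
uncertainty of the estimated intercept; when the difference is
significant the corrected estimate is the one to report. Correctness is
a simulation-recovery contract — bias removal under known overlap,
confounding and selection — not numeric identity with any external
implementation.

**Phenotyping edge case.** A person whose only fall codes are of the
excluded (non-balance) category is dropped from both cases and controls:
removing such codes from the case definition while disqualifying
controls on *any* fall code leaves no other assignment consistent with
both rules. Deduplication is per calendar day. Vocabulary–source
mismatches (ICD-10 outside HES, Read outside GP) are rejected with a
warning rather than coerced.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use sizes chosen so each
check is statistically decisive on one CPU: two-sample recovery at
k = 30 instruments with exposure/outcome GWAS of n = 20,000; one-sample
recovery at n = 20,000 individuals × 80 variants; LDSC recovery at
m = 2,000 variants × n = 20,000 (5 replicates averaged in the acceptance
script); overlap correction over 200 replicates of 1,000-variant tables;
null calibration over 1,000 replicates; the stratified negative control
at n = 10,000. Oracle checks (closed-form IVW/Egger, brute-force
weighted-median interpolation, direct penalised-likelihood maximisation
for Firth, all-pairs LD scores) run on fixtures of ≤ 50 rows at
tolerances 1e-6–1e-10.

## Known limitations

- Observed-scale h² only; the liability transform needs an externally
  supplied population prevalence.
- The event-log generator cannot create conflicting phenotypes (a case
  with zero fall records), so the phenotyping round-trip tests
  consistency, not robustness to corrupted records.
- WM/PWM bootstrap SEs ignore weight re-penalisation per draw for PWM
  (penalised weights are held fixed), a second-order effect.
- The overlap correction assumes the polygenic prior is roughly right;
  gross model misspecification (e.g. a single Mendelian locus) would
  degrade the shrinkage.
- No MR-PRESSO, mode-based estimators, multivariable MR, or Steiger
  filtering; no genomic control, clumping, conditional analysis or
  meta-analysis.
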