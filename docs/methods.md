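# Methods

`cogrisk` implements dynamic lifetime risk prediction for Alzheimer's
disease (AD) from longitudinal cognitive assessments, using a two-stage
likelihood approach embedded in a landmarking scheme, together with the
synthetic cohort generator that drives all of its tests.

## The model

**Outcome.** Lifetime AD risk: the probability that a subject who is
cognitively intact at baseline develops AD before death.  The outcome is
binary per subject; death acts only as the end of the observation window
and is *not* modelled as a competing risk.  Age-bounded variants redefine
the outcome as onset before age 85 or 90, excluding AD-free subjects who
died at or before the cut (their status at the cut is not demonstrable)
and cases with onset after it.

**Stage 1 — trajectory summaries.** For each of five cognitive-domain
composites (perceptual speed, visuospatial ability, episodic, semantic
and working memory; each the mean of available per-test z-scores
standardised against the cohort's baseline mean/SD), a linear mixed model

    y_ij = x_ij' β + b0_i + b1_i t_ij + e_ij,
    (b0_i, b1_i) ~ N(0, G),  e_ij ~ N(0, σ²)

is fitted by REML, with fixed covariates x = (1, t, baseline age, sex,
education), time t in years since baseline, and subject-level random
intercepts and slopes.  Sex is coded female = 1; education is a single
ordinal covariate 0–3.  The subject's trajectory is then summarised by
the EBLUP b̂_i = G Z_i' V_i⁻¹ (y_i − X_i β̂), which shrinks toward zero
when a subject contributes few visits or noisy data.

**Stage 2 — risk model.** The ten EBLUP summaries (intercept and slope
per domain) plus baseline age, sex and education enter a logistic
regression for the binary outcome, fitted by Newton/IRLS maximum
likelihood (gradient max-norm below 1e-8, or the standard IRLS
log-likelihood plateau — which is what terminates quasi-separated
problems, where the coefficients diverge but the fitted probabilities
have converged).  Stage-1 uncertainty is not
propagated into stage 2 (point-estimate plug-in); quasi-separation is
flagged when any coefficient exceeds 30 in absolute value.

**Landmarking.** The model "at year t" uses only visits with
visit_year ≤ t — for AD cases additionally only visits strictly before
onset — capped at the 11 earliest visits per subject.  Both stages are
refit from scratch at every landmark year 0..10, so predictions update
annually as data accrue.  Sensitivity designs: 3-/4-visit schedules
(first + last + randomly chosen intermediates) and 5-/10-year prediction
horizons (cases keep visits at least that many years before onset;
AD-free subjects keep visits within 5 years of their last).

## Numerical implementation

The REML likelihood is profiled over β (GLS) and σ², leaving a
3-parameter optimisation over the log-Cholesky factor Λ of the relative
covariance G/σ² (as in lme4).  All per-iteration work runs on per-subject
sufficient statistics (Z'Z and cross-products of the y-augmented design),
reduced with 2×2 Woodbury identities batched over subjects; an analytic
gradient (d log|A| = 2 tr(A⁻¹Λ'K dΛ), dB = H + H', and the envelope
identity d rss = c' dS c at the GLS optimum) makes one objective + gradient
evaluation a handful of elementwise operations plus a single tensor
contraction.  L-BFGS-B (bounds on the log-diagonal, ftol 1e-11 for point
fits) is polished by a derivative-free Nelder–Mead pass if the line
search aborts on a flat profile.  When no subject has two visits at
distinct times (the baseline landmark), the random-slope variance is
unidentified and pinned to zero with a warning flag; constant fixed-design
columns (e.g. the time main effect at t=0) are dropped and reported.
Exactly collinear stage-2 columns (the baseline landmark makes b̂1
proportional to b̂0) are pruned by pivoted QR with coefficient 0.

**Bootstrap internal validation.** Subjects are resampled with
replacement (their visit histories travel with them) and the *entire*
two-stage pipeline is refit per resample, B = 1000 by default.  A
resample with duplicate subjects is likelihood-equivalent to integer
subject weights, which the sufficient-statistic REML, the weighted
logistic fit and a weight-expanded AUC all consume directly — this is
what makes thousands of full refits tractable on one CPU.  Replicate fits
warm-start from the original variance parameters with a looser tolerance
(ftol 1e-9), which moves the optimum by < 3e-3 in the variance
parameters and has no visible effect on replicate AUCs.  Degenerate
resamples (one outcome class, failed fit) are redrawn; more than 20%
redraws aborts.

**Confidence intervals.** Intervals are bias-corrected (BC) percentile
intervals of the replicate AUC distribution.  Refit replicates evaluated
on their own resample inherit the apparent-AUC optimism a second time,
so the plain 2.5/97.5 percentile interval is shifted upward and
undercovers the large-sample AUC (≈78% observed at n=400 in the
package's own coverage experiments); the BC median-bias correction
restores ≈85–90% coverage with two-sided misses.  Residual
undercoverage at small n stems from the point estimate's own
finite-sample optimism, which no percentile-family interval corrects;
no optimism correction is applied to the point estimate itself.

**Other estimators.** AUC is the Mann–Whitney statistic with ties
counted 1/2 (rank-based; verified against exhaustive pair enumeration).
DeLong's test uses midrank placement values with the standard
correlated-AUC variance.  Calibration uses quantile decile bins (ties to
the lower bin; fewer than 10 distinct predictions fall back to
distinct-value bins) plus the Brier score.  Stepwise domain selection is
greedy forward search on the apparent AUC at a criterion landmark
(default t* = 10), stopping when the best improvement drops below 0.001.
Statistical table tests (Kruskal–Wallis, chi-square without continuity
correction) come from scipy; statsmodels appears only as an independent
cross-check in the test suite.

## The synthetic cohort generator

Restricted clinical data cannot ship with the package, so all testing is
against a generator whose ground truth is known and whose *generative
model matches the analysis model*, making parameter recovery well-posed:
domain scores follow exactly the stage-1 mixed model, and the lifetime
outcome follows a logistic model on the *true* random effects plus
demographics.

Default study conditions (chosen once to emulate a community aging
cohort, and to place most of the risk signal in the slopes so that
discrimination grows as follow-up accrues):

| parameter | default | meaning |
|---|---|---|
| n_subjects | 2000 | cohort size |
| baseline age | N(77.5, 7.5²), clipped 55–100 | years |
| sex | 75% female | female = 1 |
| education | (0.047, 0.131, 0.178, 0.644) | ordinal 0–3 |
| domain fixed effects | (0.25, −0.03, −0.02, 0.05, 0.10) | z-units per covariate unit (age centred at 77.5) |
| G per domain | diag(0.30, 0.004) | random intercept/slope variance (z², z²/y²) |
| residual SD | 0.25 | z-units |
| risk coefficients | b0: −0.12, b1: −11, age: 0.02/y, sex: 0.10, intercept: −1.55 | log-odds of lifetime AD |
| mortality | Gompertz h₀=0.035/y at 75, slope 0.09/y | independent of cognition |
| dropout | 0.03/y | exponential |
| visits | up to 11, annual | truncated at dropout/death/onset |
| onset placement | 0.5 y + Exp(rate), rate = 0.045·exp(0.6·(−mean std. slope)) | cases only; clipped below death age |

These yield ≈26% incident AD, mean ≈6–7 visits per subject, and a fitted
AUC(t) profile rising from ≈0.54 at baseline to ≈0.70 at year 10 — the
qualitative shape of the published analyses, not their numerical values,
which come from a restricted cohort an order of magnitude richer in
follow-up.  Raw per-test scores can be emulated (each test an affine
rescaling of its domain composite plus independent noise) to exercise
composite construction.

**What the generator does not emulate:** item-level psychometrics,
practice effects, visit-time jitter, missing-at-random item missingness,
MCI as an explicit intermediate state (only the flags the eligibility
filters consume), cognition-dependent mortality, and secular or cohort
effects.  Green tests therefore demonstrate estimator correctness and
internal consistency under the stated generative assumptions — not
transportability to real registry data.

## Design choices where the design was open

* **Time scale:** the random slope is on years since baseline (not age);
  baseline age is a fixed covariate.  This keeps random effects
  comparable across subjects of different ages.
* **Standardisation anchor:** composite z-scores use the baseline-visit
  mean/SD of the analysis cohort, reused at all later visits (stats are
  returned for serialisation), so later scores stay on the baseline scale.
* **Eligibility order:** baseline impairment → non-AD dementia → late
  MCI among non-progressors (> 10 years, retained otherwise, literally
  read) → no clinical evaluation → missing demographics; each subject
  tallied at its first matching rule.
* **"Prior to onset"** is a strict inequality on age at visit.
* **Visit cap:** the 11 earliest qualifying visits.
* **Missing domains in the comprehensive model:** subjects lacking a
  whole domain are dropped from stage 2 (tallied); imputation by zero is
  available behind a flag.
* **Null-control evaluation:** apparent (in-sample) AUC of an MLE fit
  exceeds 0.5 under the null by roughly p/(2·n_events) — finite-sample
  optimism, not miscalibration of the implementation.  Null checks
  therefore use a compact single-domain model at n=4000, where this bias
  is well inside the Monte-Carlo noise.
* **Problem sizes in tests:** recovery runs use 1000–5000 subjects;
  trend and coverage checks use B=100–200 bootstrap replicates at
  n=400–2000 — sizes at which every targeted property is measurable with
  the suite's tolerances.

## Known limitations

Stage-1 estimation uncertainty is not propagated into stage 2; no
competing-risk treatment of death; no optimism-corrected (Harrell-style)
performance estimates; no censored-outcome time-dependent ROC estimators
(the outcome is a fixed binary label); single-cohort internal validation
only.  The REML fixed-effect covariance is not exposed (only point
estimates feed stage 2).
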