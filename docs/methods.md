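# Methods

## Study design being modelled

A session is one child's visit: two 15-minute smartphone tests during which
white-noise pulses are played through headphones while the front camera
tracks facial landmarks at a nominal 60 Hz. **Test I** interleaves 8
pulse-only trials with 8 trials at each of three prepulse intensities (5%,
10% and 25% of the pulse intensity; prepulse leads the pulse by 120 ms).
**Test II** delivers ten rhythmic (constant 500 ms inter-onset interval) and
ten random (inter-onset intervals 300–1100 ms) six-pulse trains, each with
two scheduled-but-omitted onsets around which anticipatory eyeblinks are
scored. Time is milliseconds from trial start and every scored interval is
half-open `[start, end)` so frame binning is unambiguous.

The exact window timings are configuration, with defaults following common
human-startle practice: baseline = the 1000 ms before the first onset;
Test I startle window `[pulse+20, pulse+500)`; Test II windows
`[onset+20, onset+400)` truncated at the next scheduled onset (required so
that windows remain disjoint at the 300 ms inter-onset interval). Frames in
which the face was not detected carry non-finite trace values; they are
excluded from window statistics, never interpolated, and any window with
less than half its frames detected is scored invalid.

## Outcome definitions

* **Amplitude** = `max(NEC in window) − median(NEC in baseline)`, floored at
  0 — the standard eyeblink estimator (window maximum rather than mean or
  area). NEC is normalized eyelid closure, 0 = open, 1 = closed.
* **Responder rule**: median pulse-only amplitude ≥ 0.075; the boundary
  counts as a responder. Non-responders are excluded from %PPI summaries
  (the exclusion scope — plots only vs. all PPI statistics — is genuinely
  ambiguous in the field; here it applies to the per-subject %PPI values,
  while trial-level amplitude models keep all subjects).
* **%PPI** uses per-condition *medians* (matching the median-based responder
  rule); group summaries use means.
* **Cumulative sum** integrates baseline-corrected NEC clipped at 0 over the
  trial, in NEC·seconds; with a non-negative integrand the cumulative trace
  is monotone, so its maximum is its final value. The unit is a package
  convention — magnitudes are only comparable within this convention, so
  group contrasts, not absolute values, are the meaningful output.
* **Behavioral predicates** (all configurable in `BehaviorConfig`): screen
  avoidance = face undetected in > 50% of a trial's frames; headphone touch /
  vocalization = flag true in ≥ 1 frame; head rotation = |yaw| > 15°
  sustained ≥ 100 ms; side-eye gate |yaw| > 5°, scored as the rectified
  counter-rotation `max(0, −sign(yaw)·pupil_x)`; mouth-open episodes = runs
  above the session median + 1.5 units. Baseline-variability regression: per
  trial, v_t = sample SD of baseline NEC ×100; OLS v_t = a + b·t across the
  session; the *intercept* outcome is the prediction at the centre of trials
  1–5 (a + 3b) and the *SD* outcome is the residual SD. SDs use the sample
  (n−1) convention throughout. The ×100 scale and these thresholds are
  explicit reconstructions, not claimed to equal any specific deployment
  bit-for-bit.

## Statistical models

Trial-level amplitudes and cumulative sums: linear mixed model with a
per-subject random intercept, REML, Wald 95% CIs; p values use a residual
approximation t(n_subjects − k). A singular random-effects fit falls back to
OLS and is flagged. Within-group stimulus/trial effects use Type-III Wald F
tests on the fitted model. Trial-level binary behaviors: binomial logistic
regression with a per-subject random intercept fitted by maximum likelihood
with 25-node Gauss–Hermite quadrature (covariates are subject-constant, so
the likelihood aggregates to per-subject binomial counts); this
implementation agrees with `lme4::glmer` (adaptive quadrature) to ~2 decimal
places on test fixtures, and complete separation triggers a weak Gaussian
ridge on the slopes, flagged in the output. Inference for this family is
deliberately split: the coefficient, odds ratio and Wald CI come from the ML
fit (with a subject-level sandwich covariance), but the diagnosis-term
*p value* is computed from a subject-level empirical-logit regression with
HC3 covariance. The reason is a few-cluster pathology we verified by
simulation: with tens of subjects, Wald and likelihood-ratio p values of
binomial mixed models reject a true null 3–5 times too often — also when
fitted with `lme4::glmer`, and also when the random-effect distribution is
exactly logit-normal — whereas the cluster-level aggregate test holds its
nominal 5% level (400-repeat null simulations) while losing no practically
relevant power at the study's effect sizes. Subject-level scalars
(variability measures, Pearson r, behaviors 4–10): OLS. Standardized β is
the coefficient after z-scoring outcome and predictor; odds ratios replace β
for the logistic family. Holm's step-down adjustment is applied within each
outcome family (3 prepulse amplitude contrasts; 10 behaviors; etc.). Every
contrast is fitted unadjusted and age+sex-adjusted, reported side by side.

Cohort description: Fisher exact for success × diagnosis, Pearson chi-square
*without* continuity correction for sex × diagnosis (the convention that
reproduces the reference table's printed statistic), Wilcoxon rank-sum with
continuity correction for age, W reported in the Mann–Whitney-U convention
of R's `wilcox.test` and effect size r = Z/√N.

## Synthetic cohort generator

The generator emulates the study conditions — two diagnostic groups whose
group-level outcome distributions match configured means/SDs for every
endpoint — so the whole pipeline closes the loop: what the generator is told
to produce, the extraction stages recover.

* **Eyelid trace** = resting level (0.05) + a one-sided "folded" baseline
  wiggle (brief partial closures from an open lid), rescaled so its sample
  SD over detected baseline frames equals the trial's variability draw
  exactly, + a gamma-shaped startle transient (shape 3, scale 40 ms, peak
  latency 80 ms) at each pulse onset, + a small smooth post-stimulus noise
  (SD 0.005). The post-stimulus segment sits at the realized baseline
  median, which makes window-max-minus-baseline-median amplitudes unbiased
  estimators of the injected peaks. The baseline wiggle being confined to
  the pre-stimulus window is a deliberate nonstationarity: it decouples the
  baseline-variability targets from the amplitude targets, at the cost of
  realism no downstream statistic depends on.
* **Amplitudes**: per trial `clip(μ̃ + u_i + e, 0, U)` where u_i is the
  subject intercept (half the latent variance by default), e is trial noise
  and U is the trial's ceiling (full closure minus the expected baseline
  level). (μ̃, σ̃) are solved by *moment matching the doubly censored
  normal* so the observed amplitude has exactly the configured mean and SD —
  necessary because a mean of 0.33 with SD 0.34 on a [0, ~0.85] support
  forces mass at both the floor and the ceiling. Long-term habituation tilts
  the pulse-only means by the configured slope per trial pair
  (moment-matched per pair); Test II sensitization multiplies per-pulse
  means (default: +15% at pulse 3 of the random train for the autism group).
* **Binary behaviors**: per-subject event probabilities from a
  *moment-matched logit-normal* whose mean and across-subject SD reproduce
  the configured targets. Logit-normal (rather than beta) overdispersion
  makes the generated events exactly the world the random-intercept logistic
  model assumes, so the estimation model is correctly specified by
  construction. Event counts are apportioned by the largest-remainder
  method at the cohort level (totals match Σ n·p_i to within one), and
  events are materialized as contiguous flag/trace episodes (500 ms flags;
  300 ms yaw excursions of 25°; screen-avoidance chunks covering 60% of the
  trial anchored at trial start or end, so scoring windows are either fully
  present or fully absent).
* **Continuous behaviors**: subject latents from moment-matched censored
  normals; bounding-box noise is rescaled per trial to unit sample SD so the
  session SD recovers the subject's postural latent exactly; the mouth trace
  is shifted so its session mean equals the subject latent, with a
  stimulus-locked mouth transient (autism group only) added before the
  shift; the pupil curve is affinely mapped per trial onto ±h, with h solved
  in closed form so the expected per-trial excursion equals the subject's
  pupil-range latent given their realized count of yaw events; side-eye is
  expressed during head rotations and during four brief sub-threshold
  "glances" per subject (10°, 150 ms — below the rotation predicate), so
  the trait is observable for every subject.
* **Couplings**: baseline level and baseline residual scale are comonotone,
  as are pupil range and side-eye (each pair shares one quantile grid).
  Without these couplings some subjects would be assigned physically
  incoherent combinations (e.g., side-eye excursions larger than their whole
  pupil range). All other metrics are independent given the group — real
  data will have richer correlation structure, so passing tests demonstrate
  pipeline correctness, not biological realism.
* **Variance reduction**: subject latents are drawn by stratified
  (quantile-balanced) sampling with one independent random permutation per
  metric; event-probability cohorts are additionally conditioned on their
  exact target mean (the heavy logit-normal tail otherwise dominates the
  sample mean of rare events), and Test I trial noise uses antithetic +z/−z
  pairs within each (condition, trial-pair), which cancels most of the
  trial-noise contribution to cohort means without changing the marginal
  amplitude distribution. Cohort means therefore concentrate on the
  configured targets at n = 150/group even for rare events (e.g., a 0.43%
  vocalization rate), which is what makes 10%-level recovery checks
  meaningful at that size.
* **Null cohorts** (`generate_null_cohort`) pool 2n stratified subjects from
  a *single* parameter set and assign diagnosis labels at random. Under
  label randomization the model-based tests retain their nominal type-I
  error (randomization validity), whereas stratifying each arm separately
  would make them conservative. The richer-event autism parameter set is
  the default null base so the logistic endpoint has events to model.

Demographics (age bands, sex ratios, co-occurring-condition mix) follow the
reference cohort's composition per group and are outcome-neutral by default.
Fixed seeds make every session bit-reproducible; cohort manifests record the
seed, per-subject seeds and a parameter hash sufficient to re-run the
pipeline byte-identically.

## Problem sizes and numerical choices

Parameter-recovery runs use n = 150/group at 60 Hz (~30 s end to end); the
type-I-error study uses 200 null cohorts of n = 20/group at 30 Hz — sizes
chosen so the full loop stays desk-scale while keeping the binomial SE of an
empirical 5% rejection rate near 1.5 percentage points. Moment-matching
solvers (`fsolve`) are cached and validated to 1e-6; ill-posed per-subject
baseline distributions (level ≪ residual scale) are avoided by the
comonotone coupling, with latents floored at 0.5 (level, ×100 NEC) and 0.3
(residual). Degenerate inputs: zero-variance amplitudes give r = missing
(not 0); fewer than 2 valid trials give missing SDs; fewer than 6 usable
baselines give missing baseline-regression outcomes; an empty window or an
all-missing trial propagates NaN, never zero.

## Known limitations

* Generated metrics are independent between domains given the group; no
  within-subject correlation between, say, PPI and vocalizations.
* The logistic ceiling of NEC truncates extreme startle transients; the
  injection model accounts for this on average (ceiling-aware clipping), but
  per-trial ceilings vary with baseline variability, leaving residual bias
  well under the sampling noise at n = 150.
* Kernel peaks sampled at 30 Hz undershoot the analytic peak by up to ~3%;
  at the 60 Hz default the error is < 0.2%.
* The cumulative-sum unit (NEC·seconds) is internal; absolute magnitudes are
  not comparable across other conventions.
* The co-occurring-condition flag is assigned but outcome-neutral; condition
  sub-analyses are out of scope.
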