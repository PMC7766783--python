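# Methods

This note documents the models implemented in `stopbayes`, the defaults
and why they were chosen, the numerical schemes, and what the synthetic
validation does and does not establish.

## Task and race model

A stop-signal session interleaves go trials (~75%) with stop trials
(~25%), categories drawn i.i.d. (no block structure is modeled). On stop
trials a stop signal follows the go signal at the stop-signal delay (SSD),
which a one-up-one-down staircase adapts across stop trials: +67 ms after
a successful stop (SS), −67 ms after a failed stop (SE), starting at
200 ms. SSDs are clamped to [0, 1500] ms — the task itself states no
bounds, but an SSD cannot be negative and 1500 ms exceeds any delay a
staircase tracking ~50% stopping will visit with realistic reaction times.

Behavior comes from an independent horse race:

* go finish time `T_go ~ exGaussian(μ, σ, τ) + g · p(Stop)`, with defaults
  μ = 505 ms, σ = 60 ms, τ = 165 ms, chosen so the median go RT is
  ≈ 628 ms, the scale typical of adult SST cohorts. The ex-Gaussian is the
  standard right-skewed RT family. `g` (``proactive_gain_ms``) linearly
  couples the current stop expectancy to go slowing — the simplest
  mechanism that produces a positive sequential effect; `g = 0` disables
  it (the default for a bare `RaceParams`).
* stop finish time `T_stop = SSD + Normal(SSRT_true, SSRT_sd)`, defaults
  200 ms and 30 ms. The subject responds on a stop trial iff
  `T_go < T_stop`.
* go responses are omitted with probability 0.02, mirroring a ~98%
  go-response rate.

Negative sampled times are clamped to 1 ms; non-finite draws are
resampled. Sessions are ~100 trials at a 6 s trial pacing (a 10-minute
functional run of 300 volumes at TR = 2 s).

**A measured property worth knowing.** The staircase's stationary mean SSD
sits slightly *above* the exact 50% delay: the ex-Gaussian psychometric
function P(respond | SSD) is flatter above the tracking point than below
it, so the random walk lingers on the high side. Under the defaults the
exact Markov stationary mean is ≈ 440 ms where the true 50% point is
≈ 429 ms. Consequently SSRT estimates built on the staircase mean run
≈ 10–15 ms low. This is a property of the estimator under staircase
tracking, not an implementation artifact; the recovery suite tests the
across-subject mean of the estimate against the generative value with a
±15 ms band that accommodates it.

## SSRT estimation

Two estimators are provided:

* **critical_ssd** (default): `SSRT = median goRT − mean SSD`, the mean
  taken over post-burn-in stop trials. Go RTs use correct (GS) trials
  only; omissions are excluded, and wrong-button go errors are not
  simulated.
* **integration**: the go-RT quantile at the observed post-burn-in
  stop-respond rate minus the same mean SSD. With the staircase tracking
  ~50% the two agree asymptotically (they differ by < 1 ms at 10,000
  trials under the defaults).

Burn-in discards the first 10 stop trials **of each session**: every
session restarts the staircase at 200 ms, and the climb to the tracking
region would otherwise drag the mean SSD down. `estimate_ssrt` accepts a
flat trial list (one session) or a list of sessions. At least 20
post-burn-in stop trials are required.

## The Bayesian observer

The observer believes the stop rate `r_k` persists from trial to trial
with probability α and is re-drawn from a generic Beta prior otherwise,
and that trial k is a stop trial with probability `r_k`. The predictive
density is therefore the mixture `α · posterior + (1 − α) · prior`, the
posterior multiplies in the Bernoulli likelihood, and p(Stop) — assigned
to trial k *before* its category is observed, i.e. the prior belief of an
impending stop signal — is the predictive mean. The first trial's p(Stop)
is the prior mean.

Parameters: α = 0.8, prior mean pm = 0.25 (the nominal stop frequency),
concentration scale = 10. The prior is parameterized as
`Beta(pm·scale, (1−pm)·scale)` = Beta(2.5, 7.5), which is what the
functional description (mean 0.25 at scale 10) requires; an explicit
`(beta_a, beta_b)` override is available for other shape conventions.
One parameter set is used group-wide — per-subject fits are noisy and the
resulting p(Stop) series are highly robust to the exact parameterization
(perturbing pm to 0.2/0.3, scale to 5/20, α to 0.7/0.9 leaves series
correlated ≥ 0.92 with the default on a 400-trial session).

Numerics: the α-mixture leaves the beta family for α < 1, so the density
is tracked on a uniform 1000-bin grid over (0, 1) with exact Beta-CDF bin
masses and renormalization after every update (mass error < 1e−9; p(Stop)
differs by < 1e−4 between 500- and 2000-bin grids). The α = 1 limit
reproduces conjugate beta-Bernoulli updating to < 1e−3 and serves as the
closed-form oracle; α = 0 pins p(Stop) at pm.

## Proactive-control statistics

The sequential effect is the Pearson correlation between p(Stop) and go RT
over correct go trials (the same trial set that carries the p(Stop)
modulator in the GLM); its p-value is the usual t transform. Cohort
regressions are OLS; with covariates the reported r is the partial
correlation of the predictor recovered from its t statistic. The
slope-equality test defaults to the paired form — two outcomes measured on
the same subjects against the same predictor, testing the slope of the
outcome difference, which is exact under Gaussian errors — with an
independent-samples variant `t = (b1 − b2)/√(SE1² + SE2²)` available. A
Bonferroni helper exposes the 0.05/4 = 0.0125 threshold convention used
when screening four behavior–structure regressions.

## GLM design and fitting

Designs follow the standard model-based SST analysis:

* **GLM1** anchors events at go-signal onsets (fixation onset + a 2 s
  fore-period, configurable; the fore-period is not part of the behavioral
  simulation) with modulators `RT of GS`, `SSD of SS`, `SSD of SE`, in
  that order.
* **GLM2** anchors at fixation onsets with modulators `p(Stop) of GS`,
  `SSD of SS`, `p(Stop) of SS`, `SSD of SE`, `p(Stop) of SE`, in order.

Events are zero-duration impulses on a 0.1 s lattice, convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s,
peak:undershoot 6, 32 s kernel) and its temporal derivative (finite
difference at one lattice step). Modulators are mean-centered within
condition before convolution and, by default, serially orthogonalized
against their condition's earlier columns (the convention of the major
analysis packages; toggleable, since published descriptions rarely state
it). Zero-variance modulators are dropped with a warning, as are absent
conditions. The first five volumes are discarded (onsets shift back by
5·TR); a discrete-cosine basis up to the 1/128 Hz cutoff, six motion
nuisance columns (when supplied) and a constant complete the matrix.

Fitting estimates the lag-1 autocorrelation ρ from OLS residuals (per
voxel by default; a pooled option exists), applies the exact AR(1)
whitening transform (first row scaled by √(1−ρ²), so whitened OLS equals
GLS under the assumed covariance), refits, and evaluates contrasts with
t statistics on the whitened model. Residual-based ρ estimates run
somewhat low when the drift basis absorbs low-frequency noise (≈ 0.31
observed for a true 0.4 at 300 scans with ~20 regressors); β estimates
remain unbiased (< 2% mean bias over 500 replicates), which is what the
contrasts rely on.

## Mediation

Three OLS equations give the paths: total effect c (Y on X), direct
effect c′ and b (Y on X and M), and a (M on X), optionally with shared
covariates. For nested OLS on the same data `c − c′ = a·b` holds to
machine precision and is asserted on random data. Inference on a·b uses a
case-resampling bootstrap (default 10,000 draws, vectorized normal
equations) with a bias-corrected percentile interval; the two-sided
bootstrap p-value is the doubled smaller tail proportion, floored at
1/n_boot. M is declared a mediator when a, b and a·b are all significant
(α = 0.05 two-sided), *complete* when c′ additionally is not — and the
declaration is gated on the X–Y and X–M correlations being significant in
the first place, since the test is meaningless otherwise. Degenerate
resamples are redrawn and counted.

## Synthetic cohort

`CohortSpec` defaults describe a 149-subject adult cohort: 83/149 women,
ages from a truncated normal (mean 31.6, SD 11.9, range 18–72), four
100-trial sessions per subject with a three-subject minority completing
one fewer. Subject traits — true SSRT (206 ± 37 ms), go-RT shift
(± 119 ms), proactive gain, anterior/posterior gray-matter volume and two
contrast betas — follow a single-factor Gaussian model
`trait = ρ·z_age + √(1−ρ²)·ε`, which achieves each target age correlation
and is positive semi-definite by construction. Default targets: age–SSRT
0.2671, age–goRT 0.1671, age–sequential-effect −0.0510 (effectively
preserved proactive control), age–GMV −0.2554/−0.2486; the β targets
(−0.26 for the stopping contrast, +0.30 for the expectancy response) are
set to plausible magnitudes consistent with the reported directions, since
no printed values exist for them. The proactive gain default (400 ±
100 ms per unit p(Stop)) makes individual sequential effects ≈ 0.15 —
significant within a subject at ~300 go trials, as observed empirically;
noise scales are otherwise free parameters chosen at realistic magnitudes.

`mediation_mode` replaces the age/GMV/SSRT corner of the factor model with
an explicit causal chain (age → anterior GMV → SSRT) with controllable a,
b and direct effects, so the mediation stage can be validated for both
power and false-positive calibration. GMV and β values never feed back
into the behavioral simulation except through this declared structure.

`generate_voxel_bold` produces `Y = X·β + stationary AR(1) noise` for GLM
validation.

What the synthetic study does **not** emulate: block structure and
fatigue, wrong-button go errors, RT drifts, scanner physiological noise,
spatial structure of images (no volumes are synthesized — regional GMV
and β are scalar stand-ins), and attrition. Passing the recovery suites
therefore shows the estimators are correct under the stated generative
assumptions, not that those assumptions exhaust real data.

## Problem sizes and reproducibility

Default validation sizes: 50–100 subjects × 400 trials for staircase
tracking; 60–80 subjects for SSRT recovery; 500 noise replicates for GLM
bias; 120 replicate cohorts × ≥1000 bootstrap draws for mediation
calibration — sizes at which the Monte-Carlo error is comfortably below
each tolerance. Every stochastic component takes an explicit seed
(sub-seeds derived via `numpy.random.SeedSequence`), and the end-to-end
pipeline (`stopbayes run-all`) is byte-reproducible for a fixed seed; the
resolved configuration is written next to the outputs.

## Known limitations

* The staircase-mean SSRT estimators carry the ≈ −13 ms bias described
  above whenever the go distribution is right-skewed; parametric
  race-model likelihood fitting (out of scope) would remove it.
* Trial-wise p(Stop) uses one fixed parameter set; subjects with strongly
  atypical expectancy dynamics are not modeled.
* The GLM stage fits numeric voxel tables, not image volumes; spatial
  preprocessing, whole-brain inference and familywise-error correction
  are out of scope. The anterior/posterior split at MNI y = −22 is kept
  only as a coordinate-labeling utility, with the boundary plane assigned
  to *anterior* (a documented convention; the split itself is stated
  without a tie rule).
* Mediation inference is the standard product-of-paths bootstrap; causal
  interpretation still rests on the usual no-confounding assumptions.
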