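# Methods

This note documents the generative models, analysis conventions, numerical
choices and calibrations behind `contextwm`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Experiment designs

A design partitions a vocabulary into `n_sets` context sets of
`words_per_set = 12` words. The behavioral design uses six scene contexts
(72 words); the imaging design uses four contexts — face/scene × left/right,
each combination exactly once (48 words).

**Learning schedule.** Every word is presented exactly `repetitions = 3`
times, always in quadruples drawn from its own set. Trials are built per
set by shuffling the word-slot multiset (12 words × 3 repetitions) into
groups of four and rejecting groupings with a repeated word inside a trial;
set order is then shuffled globally. This is the simplest scheme consistent
with "companions randomly sampled from the same set" under the exact
repetition quota. Note the arithmetic: 6 sets × 12 words × 3 / 4 = 54
learning trials for the six-set design. The per-word repetition count is
the constraint the downstream analyses depend on, so the generator enforces
it exactly.

**Free-recall sequence.** 18 trials per distraction condition (none /
break / full), randomly intermixed; the context changes on every trial
(each trial's context is drawn uniformly from all contexts except the
previous trial's). That constraint makes the *previous-target* and
*same-context* error pools provably disjoint: 4 + 8 + 56 = 68 candidate
nontarget words on every trial.

**DNMS sequence.** Equal numbers of target, lure and other-context probes
(20/20/20 at the default 60 trials). A constant-"mismatch" responder is
correct on exactly 2/3 of trials; that rate is the below-chance exclusion
threshold.

**Overlap.** For a probe word p and target set T, overlap is the number of
(learning-trial, target) pairs in which p was co-presented with a member of
T \ {p}: Σ over learning trials containing p of |companions ∩ (T \ {p})|.
With 3 presentations × 3 companions the attainable range is 0–9. Counting
at pair level (rather than trial level, max 3) is the only reading
consistent with observed overlap ranges up to 7.

## Generative behavioral model

**Reinstatement trace.** Each trial × period (target presentation, delay,
probe presentation) × context gets an intensity in [0, 1]:
baseline 0.30 everywhere, + boost 0.50 for the target-set context, + N(0,
0.10²) noise, clipped. During the delay the boost is multiplied by the
subject's *memory strength* m ~ Beta(1.5, 5.44) (mean 0.216) — a subject
who never learned the context reinstates nothing specific. The same m
drives the posttask memory test, so the behavioral memory score and the
neural gating share a common cause (this is what gives Model 1 its
memory × lure interaction).

**Reaction times** (ms scale, additive Gaussian noise):

```
RT = μ + b_subject + β[probe type]
     + γ_probe   · e(probe ctx, delay) · 1[mismatch trial]
     + γ_overlap · e(probe ctx, delay) · overlap · 1[lure trial]
     − γ_nonprobe · mean e(nonprobe ctxs, delay)
     + ε,    ε ~ N(0, σ²)
```

Defaults: μ = 910, b ~ N(0, 100²), σ = 150, accuracy 0.95, timeout at
4000 ms (slower draws become no-response trials), γ_probe = 35 ms/unit,
γ_nonprobe = 60 ms/unit (nonprobe-context reinstatement *speeds*
responses), γ_overlap = 0 by default (plantable for recovery runs).
Modeling RT in ms with additive noise keeps the mixed-model coefficients in
ms, the scale on which effects of tens of ms are interpretable; the zRT
pipeline still log-transforms. The functional form linking reinstatement to
RT is a modeling choice mirroring Model 2's linearity; the phenomenon
itself fixes only the sign structure.

**Calibration of the probe-type offsets.** β_other = 0 (reference),
β_lure = 19.2, β_target = −1.8. These were set so that, combined with the
evidence couplings (which already slow lures, because the probe context of
a lure is the boosted target context), the cohort-level mean zRTs land on
the reference condition means +0.14 / −0.11 / −0.03 (lure / target /
other). The calibration was done analytically from the log-scale SD
(σ/μ ≈ 0.17) and refined once against a 600-subject cohort.

**Recall errors.** Per trial the number of substitutions is
Binomial(4, p_condition) with p = .016 / .080 / .151 (none / break / full),
calibrated so per-subject mean error counts match the reference cohort
(≈1.2 / 5.8 / 10.9 errors over 18 trials). Each error's word is drawn from
the category mixture (w_prev, w_same, w_other) = (.48, .31, .21); on the
first trial, which has no previous-target pool, that mass is reassigned
proportionally. Correct recalls are 4 − n_errors.

**Memory test.** Each of the 48 words is judged against the four contexts:
known with probability m (the subject's memory strength), otherwise a
uniform guess; group accuracy is therefore E[m] + (1 − E[m])/4 ≈ 41.2% at
the default Beta mean. Confidence (1–4) is drawn higher for correct
responses (Binomial(3, .75) + 1) than incorrect (.35).

## Synthetic BOLD

Voxels are abstract features: class patterns are unit-norm vectors
`shared + selectivity × class-specific` (selectivity 0 ⇒ identical patterns
⇒ nothing to decode). No spatial geometry or smoothing is simulated — the
analyses are pattern-based and geometry is irrelevant to their correctness.

The localizer has 24 miniblocks (8 kinds × 3: face/object/scene/scrambled ×
left/right), each 10 stimuli × 2 s = 20 s, separated by 12-s intervals,
with a 12-s lead-in; TR = 1 s. The task run per trial: targets 2 s, delay
18 s (probe onset at 20 s), probe 4 s, ITI 6 s. During each period every
context's pattern enters the neural signal with amplitude
`amp0 + amp_scale × trace intensity`.

Neural time series are convolved with a double-gamma HRF (positive lobe
Gamma(6, 1), mode 5 s, consistent with the pipeline's fixed 5-s shift;
undershoot Gamma(16, 1)/6; peak normalized to 1). Noise is AR(1) (ρ = 0.3)
plus white Gaussian. The default selectivity/noise pair (0.6 / 1.0) puts
4-fold cross-validated decoding near two-thirds correct — the regime of
category-selective visual ROIs — rather than at ceiling. A high-pass step
(discrete-cosine regression, 128-s cutoff) and a first-N-volume discard are
available for real data; synthetic runs do not need them.

**Amplitude-transfer calibration (recovery configuration).** Recovering a
planted coupling *in ms per evidence unit* requires the decoder's
probability readout to track the latent intensity with unit slope. The
low-noise recovery configuration (`low_noise_bold_params()`: selectivity
3.0, localizer noise 0.6, task noise 0.02, amp_scale = 1.8) pairs with a
strong ridge (λ = 50, `RECOVERY_RIDGE`) that keeps the logistic outputs in
their linear range; the scale constant was calibrated once so that the
within-subject regression of decoded delay evidence on latent intensity has
slope ≈ 1 (a constant offset is absorbed by regression intercepts). The
one-vs-rest readout necessarily carries negative crosstalk from the other
contexts' intensities; under the default couplings this aligns with the
generative structure (nonprobe reinstatement genuinely speeds RTs), so the
delay coefficient is recoverable rather than attenuated into its own CI
floor.

## Decoding conventions

- TR t is labeled class c iff t ∈ [block onset + 5 s, block end + 5 s),
  half-open; object and scrambled blocks are never used for training.
- Folds: labeled TRs are split into 4 contiguous temporal segments at
  miniblock boundaries; no block straddles folds.
- Training sets are class-balanced by deterministic evenly-spaced
  subsampling. Without balancing, fold-wise class imbalance biases the
  argmax readout against classes over-represented in the held-out fold, and
  permutation nulls sit visibly below the 25% analytic chance.
- The permutation null permutes labels at TR level *within the training
  data* and scores the held-out fold against its true labels. Permuting
  whole miniblocks instead leaves the true class signal anti-associated
  with the shuffled labels (anti-learning) and the null lands at ~22–24%
  depending on the block arrangement; the TR-level convention is centered
  on 25.0% (±0.5 across arrangements).
- Trial-period windows: raw window [onset + 5 s, onset + 11 s) per period.
  TRs claimed by an earlier period's raw window are dropped from later
  windows, and each non-first window then drops one leading TR. At TR = 1 s
  this yields target {5..10}, delay {12}, probe {26..30} relative to trial
  onset — the delay estimate deliberately comes from uncontaminated TRs
  only. The rule is config-overridable (`shift_s`, `window_s`, `gap_trs`).
- Evidence scalars per trial × period: probe-context evidence, target-
  context evidence, and mean nonprobe-/nontarget-context evidence, obtained
  by projecting the four class outputs through the design's context → class
  map.

## Statistical analyses

**Bootstrap chance analysis.** Per iteration, each subject's n observed
errors are replaced by uniform draws over the 68 candidate words — the
category count is then exactly Binomial(n, k/68), which is how it is
sampled — and counts are averaged across subjects. B = 10,000; one-sided
add-one p = (1 + #{null ≥ observed})/(B + 1); an empty error set returns
p = 1 with a degenerate flag. Resampling is per subject, then
group-averaged.

**zRT pipeline.** Subjects strictly below 2/3 accuracy are excluded (ties
retained); timeouts are removed; inaccurate trials are excluded from RT
analyses but retained for accuracy summaries. zrt = (ln RT − subject mean)
/ subject SD (ddof = 1) over included trials; the pipeline is invariant to
rescaling a subject's RTs. Probe-type contrasts are paired two-sided t
tests on per-subject condition means.

**Memory split.** TargetMemoryScore is the count (0–4) of target words
assigned to the correct context; a trial is "learned" iff score/4 > 0.5.
Both codings are decisions, not given facts; the count is what Model 1
consumes.

**Mixed models.** Gaussian random intercept per subject, REML, via
statsmodels MixedLM. Trial type uses treatment coding with *other-context*
as reference; memory score and overlap enter uncentered (main effects
interpretable at 0). Inaccurate and timeout trials are excluded from all
models. p-values and 95% CIs use the Wald normal approximation by default;
a residual-df t option (`df_method="residual"`, dof = n − k_fe − n_subjects)
is provided since no Satterthwaite machinery exists in the stack. Numerics:
the model is fit on unit-scaled endog/exog with explicit starting values
(OLS fixed effects + a moment estimate of the intercept variance) and the
estimates transformed back — without start values the optimizer can report
convergence with corrupt fixed effects when the variance estimate sits on
the zero boundary.

## Calibration experiments shipped with the package

- **Null calibration** (`analysis/06`, acceptance suite): with all planted
  effects zeroed, each test in the chain — three condition t tests, three
  probe-type contrasts, the headline terms of Models 1–3 (fit on
  latent-trace evidence) — rejects at ≈5%. The suite uses 600 replicates at
  reduced size (15 recall subjects; 10 DNMS subjects × 30 trials).
- **Parameter recovery** (`analysis/05`, acceptance suite): 50 replicates
  of 12 subjects × 60 trials under the low-noise recovery configuration;
  the Model-2 delay CI covers the planted 35 ms/unit coupling in ≥90% of
  replicates. The low-noise settings (σ = 40 ms, trace SD 0.15) are chosen
  for statistical power at this cohort size, so the check is informative
  rather than vacuous.
- **Monotonicity**: decoding accuracy is increasing in pattern selectivity,
  and the fitted delay coefficient is increasing in the planted coupling
  {0, 15, 35} ms/unit, using paired common random numbers across seeds
  (the same cohort, traces and decoded evidence per seed; only the planted
  coupling differs).

## What the generator does and does not emulate

It emulates the statistical structure the analyses assume: context-set
designs and quota-exact learning schedules; condition-dependent error rates
with category-structured substitutions; near-ceiling DNMS accuracy with
timeouts; lure slowing driven by a latent reinstatement trace gated by
memory strength; category-selective multivoxel patterns with HRF dynamics
and AR(1) noise; and the coupling between delay-period neural evidence and
RT. It does not emulate: head motion, physiological noise, spatial
structure or smoothing, eye movements, vocal-response acoustics,
serial-position effects in recall, drift-diffusion-style decision dynamics,
or practice/fatigue nonstationarities. Passing tests therefore certify the
*analysis chain* — its arithmetic, exclusion rules, calibration and
recoverability — not the neuroscience of any particular real dataset.

## Problem sizes

Default study-scale runs are 15 subjects (recall), 80 subjects × 60 trials
(RT cohort), and 12–36 subjects for imaging cohorts. The shipped test suite
and drivers use those sizes or modest reductions (e.g., 10 × 30 for null
replicates, 48 synthetic voxels), chosen so the full chain including 600
null replicates and 50 recovery replicates runs on a single CPU in
minutes.
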