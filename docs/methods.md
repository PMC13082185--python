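# Methods

`vibereach` implements a Bayesian analysis chain for single-joint (elbow)
VR reaching experiments in which muscle–tendon vibration biases
proprioceptive velocity feedback. This note documents the models, the
synthetic-data generator, the sampler, and the numerical and design
choices, in enough detail to reproduce or audit any number the package
prints.

## Experimental structure being modelled

Three task layouts, 17 participants by default:

* **Task 1** (extension reaches, visible virtual arm): 5 visual speed
  gains (−12, −6, 0, +6, +12%) × 4 vibration conditions (none, agonist,
  antagonist, both) × 18 repetitions = 360 trials/participant. Outcome:
  a binary rating of the virtual arm as *Faster*/*Slower* than the real
  arm, plus trial mean movement speed (mms, °/s).
* **Task 2** (invisible arm, point at the target): 4 vibration
  conditions × 24 repetitions × 2 movement directions (extension,
  flexion) = 192 trials/participant. Outcomes: signed endpoint error
  (epe, °, negative = undershoot), mms, and movement time (mt, s).
* **Task 3** (80° extensions): antagonist vibration switched on or off
  20° into the movement, 48 trials × 4 conditions (none, 0–80°, 0–20°,
  20–80°); 90 Hz controller positions are recorded. The estimand is the
  latency from the (hardware-corrected) vibration state change to the
  movement-speed adjustment.

Target distances are uniform on 40–80° (fixed 80° in Task 3).

## Models

All models are hierarchical Bayesian regressions with weakly
informative, zero-centred priors on effects, sampled with a No-U-Turn
Sampler (see *Inference*). Every population-level predictor also gets a
participant-level deviation unless noted.

### Rating model (Task 1)

`rating_i ~ Bernoulli(Φ(z_i))`, `z_i = β0 + β1·vg_i + β2·agovib_i +
β3·antavib_i`, with the visual gain `vg` in units of +6% so β1 is the
latent shift per gain step. This is a latent-threshold
(signal-detection-style) model: a standard-normal internal comparison
variable crosses a threshold at zero. Priors: effects N(0, 1) on the
latent (z-normalised) scale; participant-level SDs HalfNormal(1).
`predict_probability` maps draws of z to response probabilities through
the exact normal CDF; `plugin_probability(p0, δ) = Φ(Φ⁻¹(p0) + δ)` is
the fast point-estimate version.

### Task-1 speed model

`mms_i ~ N(z_i, σ)` with predictors gain, both vibration flags and
centred target distance, after centring mms within participant by the
no-vibration/no-gain condition mean. Prior scales are set from the SD of
the centred outcome (2.5·SD on effects, HalfNormal(SD) on random-effect
SDs, HalfNormal(2.5·SD) on σ): weakly informative at whatever unit the
outcome arrives in.

### Task-2 joint outcome model

`(epe, mms, mt)_i ~ N(z_i, Σ_i)` with, per outcome k:
`z_i^(k) = β0 + β(agovib × antavib × md) + β(td × md)` (full interaction
expansion), `Σ_i = D_i C D_i`, `log σ_i^(k)` linear over the
vibration × direction cells, and `C` an unrestricted 3×3 residual
correlation matrix. Outcomes are centred within participant by the
no-vibration condition mean. Movement direction `md` is coded
sum-to-zero (flexion +0.5, extension −0.5); direction-specific effects
are linear combinations of draws (`direction_effects`), with mt
converted to ms only at reporting. Participant-level deviations are
placed on the intercept and the two vibration main effects for every
outcome — vibration responsiveness varies across people, and omitting
those slopes would masquerade as condition-dependent residual SD.
`C` is parameterised by three unconstrained numbers via a
partial-correlation construction (tanh-mapped, always positive
definite) with N(0, 0.5) priors — a weak regularisation toward
independence comparable to an LKJ(2)-type prior.

### Integrative baseline models

On unperturbed trials only:

* rating ~ z-scored mms (+ centred td), same probit engine: does
  trial-to-trial speed variability predict the speed judgement?
* z-scored epe ~ z-scored mms × md (+ td × md), Gaussian, with
  direction-specific slopes derived from the draws.

z-scoring is within participant (and direction, for Task 2) on the
analysis subset.

### Changepoint model (Task 3)

Each intervention trial is reduced to **delta movement speed**: its
angular speed on a 23-point grid (−100…+120 ms in 10 ms steps,
time-locked to the vibration state change) minus the grid-point-wise
mean of the participant's matched control condition (20–80° vs none;
0–20° vs 0–80°). Grid time zero is the software trigger at the 20°
crossing plus the measured 118.8 ms trigger-to-vibration hardware delay.

The likelihood blends two per-participant linear segments with a
sigmoid of fixed 1 ms scale:

    dms_i ~ N(μ_i, σ_j),  μ_i = μpre_i·S_i + μpost_i·(1 − S_i)
    S_i = 1/(1 + exp((t_i − τ_j)/0.001))
    τ_j = τ̄ + τ_σ·ε_j,  ε_j ~ N(0,1),  τ̄ ~ U(0, 0.12),  τ_σ ~ HN(0, 0.025)

The τ hierarchy is non-centred exactly as written; individual τ_j may
leave [0, 0.12] and are flagged when more than 5% of draws do. Segment
intercept/slope priors are zero-centred normals with scales set from the
data SD (3·SD and 30·SD respectively — a slope of 30·SD per second moves
the mean by ~3·SD across the half-window); σ_j is per participant with a
HalfNormal(2·SD) prior. The 1 ms sigmoid scale is a constant of the
model, not a tunable. Analytic gradients are implemented for every
parameter and are verified against finite differences in the tests.

Degenerate-data behaviour is flagged, never hidden: a posterior SD of τ̄
above half the prior SD flags "uninformative"; a MAP within 5% of the
prior support edge flags edge-piling. Under pure noise the marginal
likelihood genuinely *favours* the prior edge (there a single line
explains all 23 points — a parsimony effect), so the edge flag, not a
prior-shaped posterior, is the expected null signature.

## Kinematic preprocessing

* **Axis of rotation**: the controller rides a circle about the elbow;
  the centre is re-estimated per trial by an algebraic (Kåsa)
  least-squares circle fit to 30 equally distributed samples. The
  algebraic fit is closed-form; tests bound its centre scatter at 1 mm
  noise by 2× a geometric (orthogonal-residual) oracle.
* **Angles**: unwrapped atan2 about the fitted centre, re-zeroed at the
  start, sign chosen so movement toward the target is positive in both
  directions. Trials whose samples stray >20% from the fitted radius, or
  with a timestamp gap over 3 nominal frames, are excluded as tracking
  issues (and counted).
* **Angular speed**: either the analytic derivative of a cubic smoothing
  spline or central finite differences followed by linear interpolation
  to the 10 ms grid. The spline's roughness penalty defaults to
  `DEFAULT_SMOOTH = 1e-7` (penalty on the integrated squared second
  derivative, angle in degrees, time in seconds), fixed so that (i) a
  linear angle is reproduced exactly, (ii) a noiseless minimum-jerk
  profile is tracked within 1% of peak speed, and (iii) group-mean
  latency estimates from the spline and finite-difference paths agree
  within 2 ms on synthetic cohorts — the concordance the analysis is
  meant to exhibit. It is a keyword argument everywhere it matters.
* **Trial summaries**: movement onset/offset are the first/last times
  speed stays above 5% of peak for ≥30 ms (both configurable);
  mt = offset − onset, mms = net angle over that window / mt,
  epe = final indicated angle − target distance.

## Synthetic cohorts

`CohortTruth` holds the generative twins of every model parameter; its
defaults are the study-scale condition effects (e.g. antagonist flexion
effects −2.76° on epe, −3.13 °/s on mms, +52.5 ms on mt; rating shifts
−0.29 and +0.41 per +6% gain; latency 48.2 ms). Extension effects are
the flexion values scaled by `ext_scale = 0.45`, matching the observed
flexion/extension asymmetry; Task-1 cohorts (extension-only) use the
values unscaled so Task-1 truths can be injected directly.

Design choices worth knowing:

* **Trajectories** are minimum-jerk (`θ(t) = start + d·(10s³ − 15s⁴ +
  6s⁵)`) — bell-shaped, smooth and analytically differentiable, so every
  kinematic stage has closed-form expectations. Durations are lognormal
  around a participant mean (default 1.1 s); baseline self-paced speeds
  are assumptions, not reported quantities.
* **Perception–action coupling**: the rating latent shares the
  standardised *self-generated* speed deviation (target-distance- and
  noise-driven, not the vibration-induced change) with weight
  `rating_speed_slope`; because the fitted baseline model's z-scored
  speed is this same quantity, the injected slope is the estimand. The
  systematic part of the latent is scaled by √(1 + slope²) so the
  marginal probit coefficients — what the rating model estimates —
  equal the stored truths.
* **Endpoint-error/speed coupling** is a residual correlation
  (`epe_speed_corr`) in the trivariate trial noise. The implied
  baseline epe_z ~ mms_z slope exceeds the correlation (speed inherits
  target-distance variance that endpoint error barely does); it is
  evaluated by a large-cohort simulation oracle
  (`implied_baseline_epe_slope`) rather than a closed form, and
  `corr_for_epe_slope` inverts it.
* **Task 3**: vibration slows the movement by `vib_speed_change`
  (−10%) from the switch time (20° crossing + hardware delay + τ_j),
  with τ_j truncated-normal in [0, 0.12] s. The velocity change is
  applied exactly (post-switch angles are an affine rescaling), so
  recovered latencies have a well-defined truth. Tracking noise
  (0.3 mm isotropic, matching the reported repeatability) is added to
  positions afterwards.
* Cohorts are byte-reproducible from (truth, seed); an optional design
  flag truncates the first participant by 194 trials to emulate the
  incomplete session (5926 included trials).

## Inference

Sampling uses a package-authored No-U-Turn Sampler (slice variant with
dual-averaging step-size adaptation, target acceptance 0.8 by default,
0.9–0.95 for the changepoint model) over hand-derived analytic
gradients. Warm-up uses the usual windowed layout: a fast step-size
interval, doubling windows each ending in a diagonal mass-matrix update
(draw variances, regularised), and a final fast interval. Models supply
posterior-scale hints that seed the mass matrix. GLMMs and the
multivariate model are sampled in an orthogonalised design basis
(mean-centred factors; cell-indicator σ design) and the draws are mapped
back to dummy-coded coefficients by an exact linear transform — same
posterior, much better conditioning. Both centred and non-centred
random-effect parameterisations are implemented (`parameterisation=`);
the non-centred form is the default and the changepoint hierarchy is
non-centred by construction.

Numerical guards: probit linear predictors are clipped at |η| = 37
(where the normal CDF saturates in double precision), log-SDs at ±200,
and the unconstrained correlation parameters at |z| = 8; all far outside
any posterior mass, they only keep divergent trajectories finite.

**Summaries.** Each scalar is reported as MAP + 95% CI: the MAP is the
mode of a Silverman-bandwidth Gaussian KDE over the draws on a 512-point
grid; the CI is equal-tailed (2.5/97.5 percentiles). R-hat and ESS come
from arviz; a fit with any reported R-hat ≥ 1.005 is flagged (returned,
never silently accepted). The full analysis profile is 4 chains × 4000
iterations including 1000 warm-up (12,000 kept draws); `REDUCED_MCMC`
(2 × 600 kept) is for simulation studies and tests.

## Validation profiles and what they show

The test suite validates the chain by parameter recovery on reduced
cohorts (4–10 participants, 3–24 repetitions per cell, reduced MCMC),
chosen so the full suite runs on a laptop-scale budget; the acceptance
script uses study-scale cohorts for Tasks 1–2 and 10 repetitions per
condition for Task 3, averaging the Task-1 and integrative-slope
estimates over three replicate cohorts. Calibration is checked as pooled 95%-CI coverage
of a null truth across replicates (the per-effect binomial bound is
applied at the pooled level at these replicate counts, with a
per-effect floor). Passing these checks shows the implementation is
internally correct and calibrated *for data generated by this model
family*; it cannot certify robustness to features real data may add —
skewed or heavy-tailed outcomes, rating lapses, tracking dropouts beyond
the modelled glitches, serial dependence across trials, or
non-stationary vibration effects.

## Known limitations

* The probit rating model has no lapse-rate parameter; a participant
  pressing the wrong button at high |gain| would bias slopes downward.
* Random-effect correlations (between participant-level intercepts and
  slopes) are not modelled; deviations are independent given their SDs.
* The changepoint model's τ_σ is weakly identified from 10 ms-grid data
  (its posterior often concentrates well below the truth while τ̄
  remains accurate); report τ̄, treat τ_σ with caution.
* The sampler is single-threaded pure NumPy; study-scale multivariate
  fits take minutes, not seconds.
* `spar`-style smoothing conventions from other environments do not map
  one-to-one onto the roughness penalty used here; match smoothing by
  the concordance property, not by copying parameter values.
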