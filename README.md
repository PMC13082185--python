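# vibereach

Bayesian analysis of vibration-biased proprioception in single-joint VR
reaching experiments.

Muscle–tendon vibration drives primary muscle-spindle (type Ia)
afferents — primarily muscle-stretch *velocity* sensors — and thereby
biases how fast a moving limb feels. In a VR reaching paradigm this
shows up three ways: the judged speed of a visible virtual arm shifts,
reaches end short (or long) of the target with correlated changes in
speed and movement time, and the motor system corrects its speed within
tens of milliseconds of a vibration switch. `vibereach` provides the
complete analysis chain for such experiments, for researchers in motor
control and psychophysics:

* a **synthetic cohort generator** with known ground truth (minimum-jerk
  trajectories, 90 Hz tracking, participant-level heterogeneity), so
  every downstream stage is testable by parameter recovery;
* **angular kinematics**: per-trial circle fits of the rotation axis,
  smoothing-spline or finite-difference angular velocity, trial
  summaries, and time-locked delta-speed grids;
* **hierarchical Bayesian models** (a package-authored No-U-Turn sampler
  over analytic gradients):
  - rating model — `rating_i ~ Bernoulli(Φ(β0 + β1·vg_i + β2·agovib_i +
    β3·antavib_i))`, a latent-threshold (signal-detection-style) probit;
  - movement-speed model — `mms_i ~ N(β0 + β1·vg_i + β2·agovib_i +
    β3·antavib_i + β4·td_i, σ)`;
  - joint outcome model — `(epe, mms, mt)_i ~ N(z_i, D_i C D_i)` with a
    full vibration × direction fixed-effect expansion, condition-
    dependent log-linear residual SDs and an unrestricted residual
    correlation matrix `C`;
  - integrative baseline models — rating ~ z-scored speed, and z-scored
    endpoint error ~ z-scored speed with direction-specific slopes;
  - changepoint model — `dms_i ~ N(μ_pre·S_i + μ_post·(1−S_i), σ_j)`
    with `S_i = 1/(1+exp((t_i − τ_j)/0.001))`,
    `τ_j = τ̄ + τ_σ·ε_j`, `τ̄ ~ U(0, 0.12)`, `τ_σ ~ HalfNormal(0.025)` —
    the latency of the reflexive speed correction.

Posteriors are summarised as MAP (KDE mode over draws) + equal-tailed
95% credible intervals, with R-hat/ESS diagnostics and an explicit
convergence rule (all R-hat < 1.005). See `docs/methods.md` for the full
model and generator documentation.

## Worked example

Fit the rating model to a simulated 17-participant cohort and map the
latent coefficients to response probabilities
(`examples/02_rating_model.py`):

```python
from vibereach import (CohortTruth, REDUCED_MCMC, fit_rating_model,
                       generate_cohort, predict_probability, task_design)

truth = CohortTruth(seed=11)      # latent truths: vg +0.41/step, antagonist -0.29
trials, _ = generate_cohort(truth, task_design(1, reps=9))
fit = fit_rating_model(trials, seed=1, **REDUCED_MCMC)
```

Output (reduced MCMC profile; one realized cohort):

```
                map  ci_low  ci_high   rhat
beta0         0.148  -0.067    0.405  1.026
beta_vg       0.259   0.135    0.414  1.012
beta_agovib  -0.032  -0.184    0.144  1.000
beta_antavib -0.365  -0.528   -0.200  1.010

P('Faster') no gain, no vibration   :  56.9%  [47.3, 65.7]
P('Faster') antagonist vibration    :  41.9%  [33.2, 51.7]
P('Faster') +6% visual gain         :  66.7%  [56.4, 76.0]
P('Faster') +12% visual gain        :  75.5%  [63.5, 85.2]
```

`beta_antavib` is the latent shift under antagonist vibration: vibration
makes the real arm feel faster, so the virtual arm is called 'Faster'
~15 percentage points less often; positive visual gain moves the
probability the other way along the probit curve. The CIs reflect a
17-participant study; with this cohort's realized participant draws the
MAPs sit within a CI half-width of the generating values.

The other examples cover cohort simulation (`01`), the joint
endpoint-error/speed/movement-time model (`03`), changepoint latency
estimation from raw tracked positions (`04`, printing ~48 ms group
latencies with per-fit convergence flags) and a full parameter-recovery
study (`05`).

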