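# Methods

This note documents the generative models, observers, analysis conventions
and design choices implemented in `adaplearn`, and what the synthetic
cohorts do and do not emulate.

## Generative processes

Both tasks produce sessions of 75 observations in normalized slider units
on [0, 1]. A hidden quantity `h_t` is piecewise constant and jumps at
change points; the flag convention is `cp_t = true` iff `h_t ≠ h_{t−1}`,
i.e. the flagged observation is the first one generated by the new regime.
The sequence start is treated as a change point for refractory accounting
(no change can occur during the first refractory observations).

* **Magnitude**: `x_t ~ Normal(h_t, 10/300)`, clipped to [0, 1] (the slider
  is a physical screen bound; at this SD and support the clipping rate is
  negligible). Hazard 1/10 per observation, zero for the 3 observations
  after a change. The hidden mean is drawn uniformly from
  `mean_support = [0.1, 0.9]` — the original interval is not documented;
  this default keeps observations almost surely on-screen and mirrors the
  probability task. It is a config field, not a constant.
* **Probability**: `x_t ~ Bernoulli(h_t)` coded 0 (yellow) / 1 (blue).
  Hazard 1/20, zero for 6 observations after a change. `h` starts uniform
  on [0.1, 0.9] and is resampled uniformly at each change point subject to
  a fourfold minimum change of the odds `p/(1−p)`, enforced by rejection
  sampling with a 10,000-draw cap (a cap hit signals an infeasible
  configuration, e.g. a tiny support with a huge odds factor).

Reproducibility: every sequence is a pure function of its integer seed;
sequence sets derive per-sequence seeds from a master seed through
`numpy.random.SeedSequence`.

## Normative observers

Both observers know the true generative parameters and compute, per
observation: the posterior-mean estimate `v_t`, the prior uncertainty
`u_t`, the change-point probability `Omega_t`, and the apparent learning
rate `alpha_t` obtained by applying
`alpha_t = (v_t − v_{t−1})/(x_t − v_{t−1})` to the observer's own
estimates with `v_0 = 0.5` (the slider starts centered).

**Probability task — grid filter.** Exact Bayesian filtering on a grid of
301 equally spaced points over [0.1, 0.9] with uniform masses (the uniform
density makes midpoint-rule masses constant). Each step first forms the
predicted prior `(1−H)·posterior + H·uniform`, then multiplies by the
Bernoulli likelihood `h^x (1−h)^(1−x)` and renormalizes.
`Omega_t = H·E_uniform[lik] / E_prior[lik]`. Doubling or halving the grid
changes no reported statistic at the tolerances used anywhere in the test
suite; a 41-point grid already matches exhaustive change-point enumeration
to 1e−6. The filter assumes a constant hazard with uniform resampling,
deliberately ignoring the generative refractory period and odds
constraint — the standard observer model for this task family.

**Magnitude task — reduced Gaussian change-point model.** A two-moment
recursion over the posterior mean `b_t` and relative uncertainty
`tau_t ∈ [0, 1]`:

    sigma_t^2 = N^2 + tau_t N^2 / (1 − tau_t)
    Omega_t   = U(x_t) H / (U(x_t) H + Normal(x_t; b_t, sigma_t^2) (1 − H))
    eta_t     = tau_t + (1 − tau_t) Omega_t
    b_{t+1}   = b_t + eta_t (x_t − b_t),   v_t = b_{t+1}
    u_t^2     = tau_t sigma_t^2
    A         = N^2 Omega_t + (1 − Omega_t) tau_t N^2
                + Omega_t (1 − Omega_t) ((b_t − x_t)(1 − tau_t))^2
    tau_{t+1} = A / (A + N^2)

`U` is the uniform change likelihood, the density 1 on the unit slider
range. `N = 10/300` and `H = 1/10` by default. Because
`v_t − v_{t−1} = eta_t (x_t − b_t)`, the measured `alpha_t` equals the
internal `eta_t` wherever the prediction error is nonzero — a
self-consistency identity the test suite checks at 1e−12.

Numerical choices: `b_0 = 0.5`, `tau_0 = 0.5` (moderate initial
uncertainty; the initialization is not documented in the literature on
this task and is configurable); `tau` is clamped to `[1e−6, 1 − 1e−6]` so
the predictive variance stays finite. At the first observation the initial
prior stands in for the "previous posterior", so `Omega_1` and `u_1` have
no well-defined prior context; every analysis in the package excludes
t = 1.

**Prior-uncertainty convention.** Two versions are exposed: `u` is the SD
of the change-point-predicted prior (the distribution actually multiplied
with the likelihood) and is the default regressor; `u_prev` is the SD of
the previous posterior before hazard mixing. For the reduced magnitude
model the two coincide by construction.

## Simulated cohorts

Agents report `v_0 = 0.5` and then one value per observation, clipped to
the slider range:

* `delta_rule` — fixed learning rate `a`; its measured learning rate is
  exactly `a`, making it the null model for dynamics analyses.
* `normative` — reports the observer's posterior mean.
* `report_noise` — normative estimate plus i.i.d. Gaussian report noise.
* `learning_noise_constant` / `learning_noise_scaled` — a *fixed-rate*
  learner whose update is corrupted by Gaussian learning noise, of
  constant SD or SD proportional to |prediction error|. These are the
  control for whether variability in the learning process alone can
  masquerade as adaptive learning-rate dynamics; the base learner is
  deliberately non-adaptive.

Noisy probability-task reports are truncated to the admissible estimate
range [0.1, 0.9] (the hidden probability never leaves it, and the task
display marks the outer bands as inadmissible). Without this, noise can
push a report next to 0 or 1 where the prediction error of a binary
observation approaches zero and the measured learning rate diverges — a
regime real reports cannot produce. Deterministic agents never need the
truncation and keep the full slider range, which preserves the exact
constancy of delta-rule learning rates.

Defaults `alpha = 0.1` and `noise_sd = 0.03` are calibrated, once, to the
scale of the data the cohorts emulate: 0.1 matches the average
probability-task learning rate of the normative observer (and of human
baselines in this task family), and 0.03 makes the noisy learner's
deviation from the normative estimate comparable to the human scale
(subject–normative correlations around 0.8). A known limitation: with
much larger rates or noise, boundary truncation asymmetrically suppresses
pre-change updates and manufactures a spurious post-change "elevation";
the noise controls should therefore be interpreted at behaviorally
calibrated noise levels.

Cohorts assign each agent a random without-replacement subset of the
sequence set, so sequences are shared across agents — the structure the
group-level decomposition requires.

## Learning-rate analyses

**Measurement and exclusions.** `alpha_t` is undefined (excluded) when the
prediction error is numerically zero (|PE| ≤ 1e−12). In the magnitude
task, learning rates outside [−0.6, 1.3] are additionally excluded as
outliers — they arise when the prediction error is near zero and the ratio
explodes. No outlier bounds are applied in the probability task, where a
binary observation and an interior report keep |PE| ≥ 0.1.

**Change-point alignment.** Offsets are change-point-relative: +1 is the
first observation generated by the new regime, −1 and −2 the two
observations before the change (there is no offset 0). The window is
−2…+8 by default. Learning rates are averaged per offset within subject
(across all change points of all their sessions; change points with fewer
than two clean pre-change observations are dropped), then across subjects.
The baseline is the mean at offsets −2 and −1.

**Cluster permutation test.** Per-offset two-tailed one-sample t-tests of
(offset − baseline); contiguous offsets with p < 0.05 form clusters scored
by summed |t|; the null distribution of the maximum cluster statistic is
built from random sign flips of whole subject difference curves (10,000 by
default, seeded). When `2^n_subjects ≤ n_permutations` all sign patterns
are enumerated, making the p-values exact — automatic for cohorts of ten
or fewer. Mean differences below 1e−9 are treated as exactly zero so that
bitwise-constant curves (delta-rule cohorts) cannot form clusters out of
floating-point rounding. The cluster statistic (summed |t|) and the
permutation count are package choices; alternatives such as cluster mass
change none of the qualitative conclusions the tests assert.

**Determinant regression.** Per subject, `alpha`, `Omega` and `u` are
pooled across all retained observations of all the subject's sessions of a
task, z-scored, and `alpha` is regressed on the two determinants by OLS
with an intercept (immaterial after z-scoring, included for numerical
hygiene). Pooling across sessions maximizes the per-subject sample; t = 1
observations and excluded learning rates are dropped before z-scoring.
Group level: two-tailed one-sample t-tests of each weight against zero and
a paired t-test of the two weights. Interaction grids use per-subject
quantile bins (defaults 2 `Omega` × 4 `u` bins for probability, the
transpose for magnitude — more bins along the factor with the wider
range).

**Bias/variance decomposition.** For each (sequence, observation) cell
with at least two subject estimates:

    mse = mean_i (v^n − v^s(i))^2
    sbe = (v^n − mean_i v^s(i))^2
    var = mean_i (mean_i v^s − v^s(i))^2

with `mse = sbe + var` exactly. Cells are summed unweighted across
observations and sequences (weighting by the number of subjects is an
option); proportions are percentages of the total. Standard errors come
from resampling *sequences* with replacement (10,000 resamples by
default, seeded). The plug-in estimators carry the usual small-sample
inflation: for an unbiased cohort of n subjects the expected bias share is
about 100/n percent, a property the test suite verifies.

## What the synthetic cohorts do and do not show

The generators reproduce the tasks' documented statistics (hazards,
refractory periods, supports, odds constraint, session length), so every
analysis stage can be exercised end to end with known ground truth:
normative cohorts reproduce the qualitative signatures the normative
analysis predicts — a sudden learning-rate peak at offset +1 for
magnitudes, a prolonged elevation through offset +8 for probabilities, and
the dominance reversal between `Omega` and `u` across tasks. They do not
emulate human report dynamics (motor delays, discretized slider moves,
autocorrelated idiosyncratic biases), so passing tests demonstrate the
correctness and sensitivity of the pipeline, not human-level effect sizes.
Published human reference points for this paradigm (subject–normative
correlations near 0.96/0.80, determinant weights near 0.43/0.14 and
0.07/0.15, bias/variance splits near 23.5/76.5% and 17.3/82.7%) require a
behavioral dataset, which can be imported through the documented session
schema.

One quantitative caveat: the pooled Spearman correlation between `Omega`
and |PE| is exactly 1 for the probability filter (given the observation,
`Omega` is a monotone function of |PE|) but tops out near 0.966 for the
reduced magnitude model, because `Omega` there depends on both |PE| and
the time-varying predictive SD. Restricting the pool to observations with
non-negligible prediction errors — as the magnitude outlier exclusions do
for subject data — raises it to about 0.99.

## Known limitations

* The magnitude observer is the reduced two-moment model; the full
  run-length posterior is implemented only as a test oracle on short
  sequences.
* The probability filter ignores the generative refractory period and odds
  constraint (deliberately, see above), so it is mildly mis-specified with
  respect to the generator.
* Learning-noise agents are descriptive controls, not fitted models of
  human learning noise; their boundary behavior at large noise is an
  artifact regime (see above).
* Session tables assume one report per observation; paradigms with sparse
  or delayed reports need resampling before import.
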