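# adaplearn

Tools for studying **dynamic adaptive learning**: how a learner should (and
measurably does) change its learning rate from one observation to the next
in a stochastic environment that changes abruptly at hidden *change points*.

The package targets two classic estimation settings with continuous,
per-observation reports:

* **Magnitude learning** — estimate the mean of Gaussian observations
  (SD 10/300 in normalized slider units) whose mean jumps at change points
  (hazard 1/10 per observation, 3-observation refractory period).
* **Probability learning** — estimate the parameter of Bernoulli
  observations (blue/yellow, coded 1/0) that jumps at change points
  (hazard 1/20, 6-observation refractory period, parameter uniform on
  [0.1, 0.9] with at least a fourfold odds change at each jump).

## The quantities at the core

The *apparent learning rate* for observation `x_t` is measured directly
from the report trace, with no model fitting:

    alpha_t = (v_t − v_{t−1}) / (x_t − v_{t−1})

where `v_t` is the report after `x_t`. Normative (Bayes-optimal) analysis
identifies two determinants of how large this update should be:

* **change-point probability** `Omega_t = p(h_t ≠ h_{t−1} | x_{1:t})`, how
  strongly the latest observation suggests the hidden quantity just changed
  (inversely related to the prior–likelihood overlap), and
* **prior uncertainty** `u_t`, the SD of the belief distribution before
  `x_t` is incorporated.

Both are computed by the normative observers implemented here: a grid-based
Bayesian filter for the probability task and the reduced (two-moment)
Gaussian change-point model for the magnitude task. Because a single
Gaussian observation is far more informative than a single Bernoulli draw,
`Omega` has a much wider range in magnitude learning and `u` in probability
learning — so the dominant determinant of the learning rate reverses
between the tasks.

## What the package provides

| module | contents |
| --- | --- |
| `seqgen` | generative processes for both tasks (seeded, serializable) |
| `normative` | the two Bayesian observers; `v`, `u`, `Omega`, `alpha` traces |
| `agents` | simulated cohorts: delta-rule, normative, report-noise and learning-noise learners |
| `metrics` | learning-rate measurement, change-point-aligned dynamics, FWE cluster permutation test, accuracy/calibration, update-frequency stats |
| `determinants` | z-scored two-determinant regression, group-level tests, interaction grids |
| `decomposition` | group-level bias/variance decomposition of deviations from normative estimates, with bootstrap SEs |
| `io` / `pipeline` / `cli` | CSV session tables, a config-driven pipeline, and the `adaplearn` command-line tool |

## Worked example

Generate a probability-task sequence set, run the normative observer,
simulate a cohort of normative agents, and analyze their learning-rate
dynamics and determinants:

```python
import adaplearn as al

seqs = al.generate_sequence_set(al.ProbabilityGenConfig(), 150, seed=0)
norms = {s.sequence_id: al.run_observer(s) for s in seqs}
print(al.measure_determinant_correlation(list(norms.values()), seqs))

traces = al.simulate_cohort(seqs, 24, al.AgentConfig(kind="normative"),
                            seed=1, n_sessions=15)
by_id = {s.sequence_id: s for s in seqs}
series = [al.compute_learning_rates(t, by_id[t.sequence_id]) for t in traces]
dyn = al.changepoint_dynamics(series, [by_id[t.sequence_id] for t in traces],
                              n_permutations=1000, seed=2)
weights = al.cohort_weights(series, [norms[t.sequence_id] for t in traces])
tests = al.group_level_tests(weights)
```

This prints / yields:

```
Spearman rho(Omega, |PE|): 1.000
offsets:     -2 -1 +1 +2 +3 +4 +5 +6 +7 +8
mean alpha:  0.10 0.10 0.11 0.13 0.13 0.13 0.13 0.12 0.11 0.11
baseline: 0.099
cluster (1, 2, 3, 4, 5, 6, 7, 8): stat=107.9, p=0.0010
w_omega = 0.434 +/- 0.003
w_u     = 0.895 +/- 0.001
paired t(23) = -241.4, p = 1.18e-40
```

Read: in probability learning the change-point probability is a monotone
function of the absolute prediction error (rho = 1); the learning rate rises
*gradually* after a change point and stays above the pre-change baseline
through the eighth observation (one FWE-significant cluster spanning
offsets +1…+8); and prior uncertainty (`w_u`) dominates change-point
probability (`w_omega`) as a determinant of the learning rate — in the
magnitude task the same analysis gives a sudden peak at offset +1 and the
reversed dominance.

The same analyses are available from the shell:

```sh
adaplearn generate --task probability -n 150 --seed 0 -o seqs.csv
adaplearn simulate --sequences seqs.csv --kind normative --n-agents 24 -o sessions.csv
adaplearn analyze dynamics --sessions sessions.csv --sequences seqs.csv
adaplearn report -o results/        # full pipeline + summary.json
```

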