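"""Normative-observer tests against independent oracles.

Oracles used here:
* closed-form moments of a truncated uniform prior (first-observation update);
* direct grid Bayes (no change points) for the hazard-0 filter;
* exhaustive marginalization over all change-point placements for short
  sequences;
* a high-precision sympy re-evaluation of the reduced-model equations.
"""

import itertools

import numpy as np
import pytest
import sympy

from adaplearn import (DataError, MagnitudeGenConfig, MagnitudeModelConfig,
                       NormativeTrace, ObservationSequence,
                       ProbabilityFilterConfig, ProbabilityGenConfig,
                       generate_probability_sequence,
                       measure_determinant_correlation, run_magnitude_model,
                       run_probability_filter)


def _prob_seq(x, config=None):
    x = np.asarray(x, dtype=float)
    h = np.full(len(x), 0.5)
    cp = np.zeros(len(x), dtype=bool)
    cp[0] = True
    return ObservationSequence("probability", x, h, cp,
                               config=config or ProbabilityGenConfig())


def _mag_seq(x):
    x = np.asarray(x, dtype=float)
    cp = np.zeros(len(x), dtype=bool)
    cp[0] = True
    return ObservationSequence("magnitude", x, np.full(len(x), 0.5), cp,
                               config=MagnitudeGenConfig())


# ---------------------------------------------------------------- probability

def test_first_observation_matches_truncated_uniform_moments():
    """After one blue draw the posterior mean is E[h^2]/E[h] under the
    uniform prior on [0.1, 0.9] (closed form ~0.6067)."""
    lo, hi = 0.1, 0.9
    e_h = (hi**2 - lo**2) / 2 / (hi - lo)
    e_h2 = (hi**3 - lo**3) / 3 / (hi - lo)
    expected = e_h2 / e_h
    trace = run_probability_filter(_prob_seq([1.0]))
    assert trace.v[0] == pytest.approx(expected, abs=2e-3)
    # symmetric case: one yellow draw
    trace0 = run_probability_filter(_prob_seq([0.0]))
    assert trace0.v[0] == pytest.approx(1.0 - expected, abs=2e-3)


def test_hazard_zero_filter_equals_direct_bayes():
    """With no hazard, sequential filtering is plain Bayes on the grid."""
    cfg = ProbabilityFilterConfig(hazard=0.0, grid_size=101)
    rng = np.random.default_rng(3)
    x = (rng.random(40) < 0.7).astype(float)
    trace = run_probability_filter(_prob_seq(x), cfg)

    grid = np.linspace(0.1, 0.9, 101)
    post = np.ones(101) / 101
    for t, xt in enumerate(x):
        post = post * (grid if xt == 1 else 1 - grid)
        post = post / post.sum()
        assert abs(trace.v[t] - grid @ post) <= 1e-10


def test_long_all_zero_stream_concentrates_at_lower_bound():
    x = np.zeros(300)
    trace = run_probability_filter(_prob_seq(x),
                                   ProbabilityFilterConfig(hazard=0.0))
    assert trace.v[-1] < 0.105
    assert np.all(np.diff(trace.v[:50]) < 0)


def _enumeration_posterior_mean(x, hazard, grid):
    """Marginalize over all change-point placements (change possible at each
    t >= 2 with prob ``hazard``, new value uniform on the grid)."""
    n = len(grid)
    liks = np.array([grid if xt == 1 else 1 - grid for xt in x])  # T x n
    T = len(x)
    total_w = np.zeros(n)
    for changes in itertools.product([0, 1], repeat=T - 1):
        prior_w = np.prod([hazard if c else 1 - hazard for c in changes])
        # segment boundaries: change at t (1-based index into x) starts a segment
        bounds = [0] + [t + 1 for t, c in enumerate(changes) if c] + [T]
        seg_factor = 1.0
        for a, b in zip(bounds[:-2], bounds[1:-1]):
            seg_factor *= liks[a:b].prod(axis=0).mean()
        last = liks[bounds[-2]:T].prod(axis=0) / n
        total_w += prior_w * seg_factor * last
    return float(grid @ total_w / total_w.sum())


@pytest.mark.parametrize("seed", range(6))
def test_filter_matches_changepoint_enumeration_on_length8(seed):
    """Posterior mean equals brute-force marginalization over all 2^7
    change configurations, on the same grid."""
    rng = np.random.default_rng(seed)
    x = (rng.random(8) < rng.uniform(0.2, 0.8)).astype(float)
    cfg = ProbabilityFilterConfig(hazard=1 / 20, grid_size=41)
    trace = run_probability_filter(_prob_seq(x), cfg)
    grid = np.linspace(0.1, 0.9, 41)
    expected = _enumeration_posterior_mean(x, 1 / 20, grid)
    assert trace.v[-1] == pytest.approx(expected, abs=1e-6)


def test_filter_rejects_nonbinary_and_wrong_task(mag_seqs):
    with pytest.raises(DataError):
        run_probability_filter(_prob_seq([0.5]))
    with pytest.raises(DataError):
        run_probability_filter(mag_seqs[0])
    with pytest.raises(DataError):
        run_magnitude_model(_prob_seq([1.0]))


def test_trace_invariants_hold_on_generated_sequences(prob_seqs, prob_norms,
                                                      mag_seqs, mag_norms):
    for tr in prob_norms:
        assert np.all((tr.omega >= 0) & (tr.omega <= 1))
        assert np.all(tr.u >= 0)
        assert np.all((tr.v >= 0.1) & (tr.v <= 0.9))
    for tr in mag_norms:
        assert np.all((tr.omega >= 0) & (tr.omega <= 1))
        assert np.all((tr.v >= 0) & (tr.v <= 1))
        assert np.all(tr.u >= 0)


# ------------------------------------------------------------------ magnitude

def test_magnitude_step_matches_sympy_high_precision():
    """One reduced-model step (b=0.5, tau=0.2, N=10/300, H=0.1, x=0.6)
    agrees with a 50-digit symbolic evaluation of the printed equations."""
    b, tau, x = sympy.Rational(1, 2), sympy.Rational(1, 5), sympy.Rational(3, 5)
    N = sympy.Rational(10, 300)
    H = sympy.Rational(1, 10)
    N2 = N**2
    sigma2 = N2 + tau * N2 / (1 - tau)
    gauss = sympy.exp(-(x - b)**2 / (2 * sigma2)) / sympy.sqrt(2 * sympy.pi * sigma2)
    omega = H / (H + gauss * (1 - H))
    eta = tau + (1 - tau) * omega
    b_next = b + eta * (x - b)
    a_num = N2 * omega + (1 - omega) * tau * N2 \
        + omega * (1 - omega) * (x * tau + b * (1 - tau) - x)**2
    tau_next = a_num / (a_num + N2)

    cfg = MagnitudeModelConfig(obs_sd=10 / 300, hazard=0.1, b0=0.5, tau0=0.2)
    trace = run_magnitude_model(_mag_seq([0.6, 0.6]), cfg)
    assert trace.omega[0] == pytest.approx(float(omega.evalf(50)), abs=1e-12)
    assert trace.eta[0] == pytest.approx(float(eta.evalf(50)), abs=1e-12)
    assert trace.v[0] == pytest.approx(float(b_next.evalf(50)), abs=1e-12)
    assert trace.u[0] == pytest.approx(float(sympy.sqrt(tau * sigma2).evalf(50)),
                                       abs=1e-12)
    # tau_{t+1} is observable through the next step's prior uncertainty
    sigma2_next = N2 / (1 - tau_next)
    assert trace.u[1] == pytest.approx(
        float(sympy.sqrt(tau_next * sigma2_next).evalf(50)), abs=1e-12)


def test_zero_prediction_error_leaves_estimate_and_flags_alpha():
    trace = run_magnitude_model(_mag_seq([0.5, 0.5]),
                                MagnitudeModelConfig(b0=0.5))
    assert trace.v[0] == 0.5 and trace.v[1] == 0.5
    assert np.isnan(trace.alpha).all()


def test_extreme_surprise_triggers_one_shot_reset():
    """An observation many SDs away gives Omega ~ 1 and a full update."""
    cfg = MagnitudeModelConfig(b0=0.5, tau0=0.01)
    trace = run_magnitude_model(_mag_seq([0.95]), cfg)
    assert trace.omega[0] > 0.999
    assert trace.eta[0] > 0.999
    assert abs(trace.v[0] - 0.95) < 0.001


def test_measured_learning_rate_reproduces_internal_eta(mag_norms):
    """Eq.-1 learning rates on the model's own estimates equal eta."""
    for tr in mag_norms:
        ok = ~np.isnan(tr.alpha)
        assert ok.any()
        np.testing.assert_allclose(tr.alpha[ok], tr.eta[ok], atol=1e-12)


# ----------------------------------------------------------- shared quantities

def test_determinant_variation_ranges_differ_between_tasks(
        mag_norms, prob_norms):
    """Omega varies more in magnitude learning; u varies more in probability
    learning (the source of the dominance reversal)."""
    def rng_of(traces, attr):
        vals = np.concatenate([getattr(t, attr)[1:] for t in traces])
        return vals.max() - vals.min()

    assert rng_of(mag_norms, "omega") > rng_of(prob_norms, "omega")
    assert rng_of(prob_norms, "u") > rng_of(mag_norms, "u")


def test_spearman_is_one_for_monotone_transform_of_error(prob_seqs):
    """Replacing Omega by any increasing function of |PE| gives rho = 1."""
    traces = []
    for s in prob_seqs[:5]:
        tr = run_probability_filter(s)
        v_prev = np.concatenate([[0.5], tr.v[:-1]])
        fake_omega = 0.1 + 0.5 * np.abs(s.x - v_prev)
        traces.append(NormativeTrace("probability", tr.v, tr.u, fake_omega,
                                     tr.alpha))
    assert measure_determinant_correlation(traces, prob_seqs[:5]) == \
        pytest.approx(1.0, abs=1e-12)


def test_empty_input_raises():
    with pytest.raises(DataError):
        measure_determinant_correlation([], [])
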