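"""Learning-rate measurement, change-point dynamics and the cluster test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from adaplearn import (AgentConfig, ConfigurationError, DataError,
                       EstimateTrace, MagnitudeGenConfig, ObservationSequence,
                       align_to_changepoints, changepoint_dynamics,
                       cluster_permutation_test, compute_learning_rates,
                       estimate_accuracy, simulate_cohort,
                       update_frequency_stats)


def _seq(task, x, cp=None):
    x = np.asarray(x, dtype=float)
    cp_arr = np.zeros(len(x), dtype=bool)
    cp_arr[0] = True
    if cp is not None:
        cp_arr[list(cp)] = True
    return ObservationSequence(task, x, np.full(len(x), 0.5), cp_arr,
                               config=MagnitudeGenConfig())


def _trace(v, subject="s0", sequence=""):
    return EstimateTrace(np.asarray(v, dtype=float), subject_id=subject,
                         sequence_id=sequence)


# ------------------------------------------------------------- learning rates

def test_learning_rate_arithmetic_and_boundaries():
    seq = _seq("magnitude", [1.0, 1.0, 0.5])
    series = compute_learning_rates(_trace([0.5, 0.8, 1.0, 1.0]), seq)
    # (0.8-0.5)/(1-0.5)=0.6 ; full update to x -> 1 ; no update -> 0
    np.testing.assert_allclose(series.alpha, [0.6, 1.0, 0.0], atol=1e-12)


def test_magnitude_outliers_are_flagged_not_valued():
    seq = _seq("magnitude", [0.6, 0.6, 0.6])
    # alphas: 1.35 (outlier), -0.7 (outlier), 0.5 (kept)
    v = [0.5, 0.5 + 1.35 * 0.1]
    v.append(v[1] + -0.7 * (0.6 - v[1]))
    v.append(v[2] + 0.5 * (0.6 - v[2]))
    series = compute_learning_rates(_trace(v), seq)
    assert list(series.excluded) == [True, True, False]
    assert np.isnan(series.alpha[0]) and series.alpha[2] == pytest.approx(0.5)
    kept = compute_learning_rates(_trace(v), seq, exclude_outliers=False)
    assert kept.alpha[0] == pytest.approx(1.35)


def test_zero_prediction_error_is_excluded():
    seq = _seq("probability", [1.0])
    series = compute_learning_rates(_trace([1.0, 1.0]), seq)
    assert series.excluded[0] and np.isnan(series.alpha[0])


def test_length_mismatch_raises():
    with pytest.raises(DataError):
        compute_learning_rates(_trace([0.5, 0.6]), _seq("magnitude", [1, 1]))


# ------------------------------------------------------------------- dynamics

def _delta_cohort(seqs, alpha=0.25, n_agents=6):
    traces = simulate_cohort(seqs, n_agents,
                             AgentConfig(kind="delta_rule", alpha=alpha),
                             seed=3)
    by_id = {s.sequence_id: s for s in seqs}
    tseqs = [by_id[t.sequence_id] for t in traces]
    series = [compute_learning_rates(t, s, exclude_outliers=False)
              for t, s in zip(traces, tseqs)]
    return series, tseqs


def test_delta_rule_dynamics_are_flat_and_nonsignificant(prob_seqs):
    series, tseqs = _delta_cohort(prob_seqs)
    dyn = changepoint_dynamics(series, tseqs, n_permutations=500)
    np.testing.assert_allclose(dyn.mean_curve, 0.25, atol=1e-9)
    assert dyn.baseline == pytest.approx(0.25, abs=1e-9)
    assert not any(c.significant for c in dyn.clusters)


def test_alignment_offsets_and_windowing(prob_seqs):
    series, tseqs = _delta_cohort(prob_seqs, n_agents=2)
    dyn = align_to_changepoints(series, tseqs, window=(-2, 8))
    assert list(dyn.offsets) == [-2, -1, 1, 2, 3, 4, 5, 6, 7, 8]
    with pytest.raises(ConfigurationError):
        align_to_changepoints(series, tseqs, window=(-1, 8))


def test_alignment_maps_first_postchange_observation_to_plus_one():
    """A lone spike at the change-point observation shows up at offset +1."""
    x = np.full(20, 0.4)
    seq = _seq("probability", x, cp=[10])
    v = np.full(21, 0.5)
    alphas = np.full(20, 0.2)
    alphas[10] = 0.9  # the first observation of the new regime
    # build a trace whose measured alphas equal `alphas`
    for t in range(20):
        v[t + 1] = v[t] + alphas[t] * (x[t] - v[t])
    series = [compute_learning_rates(_trace(v, subject=f"s{i}"), seq,
                                     exclude_outliers=False)
              for i in range(2)]
    dyn = align_to_changepoints(series, [seq, seq])
    curve = dict(zip(dyn.offsets, dyn.mean_curve))
    assert curve[1] == pytest.approx(0.9, abs=1e-9)
    assert curve[-1] == pytest.approx(0.2, abs=1e-9)
    assert curve[2] == pytest.approx(0.2, abs=1e-9)


# ----------------------------------------------------------- cluster testing

def _brute_force_cluster_p(diffs, alpha_level=0.05):
    """Independent enumeration oracle: all 2^n sign flips, max summed-|t|
    cluster statistic per flip."""
    n, m = diffs.shape

    def tp(d):
        t = stats.ttest_1samp(d, 0.0)
        return t.statistic, t.pvalue

    def clusters(d):
        ts, ps = tp(d)
        out, cur = [], []
        for j in range(m):
            if ps[j] < alpha_level:
                cur.append(j)
            elif cur:
                out.append(cur)
                cur = []
        if cur:
            out.append(cur)
        return [(tuple(c), float(np.abs(ts[list(c)]).sum())) for c in out]

    obs = clusters(diffs)
    null_max = []
    for signs in itertools.product([1, -1], repeat=n):
        d = diffs * np.array(signs)[:, None]
        cl = clusters(d)
        null_max.append(max((s for _, s in cl), default=0.0))
    null_max = np.array(null_max)
    return {c: float(np.mean(null_max >= s - 1e-12)) for c, s in obs}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cluster_pvalues_match_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    diffs = rng.normal(0.3, 1.0, size=(5, 6))
    expected = _brute_force_cluster_p(diffs)
    got = cluster_permutation_test(diffs, n_permutations=10_000)
    assert {c.offsets for c in got} == set(expected)
    for c in got:
        assert c.p_value == pytest.approx(expected[c.offsets], abs=1e-12)


def test_identically_zero_differences_give_no_clusters():
    assert cluster_permutation_test(np.zeros((6, 8))) == []


def test_injected_effect_recovers_exact_cluster_extent():
    rng = np.random.default_rng(12)
    diffs = rng.normal(0.0, 0.05, size=(12, 8))
    diffs[:, 1:4] += 1.0  # large effect at three contiguous offsets
    clusters = cluster_permutation_test(diffs, n_permutations=2000, seed=0)
    sig = [c for c in clusters if c.significant]
    assert len(sig) == 1
    assert sig[0].offsets == (1, 2, 3)
    assert sig[0].p_value < 0.01


def test_too_few_permutations_rejected():
    with pytest.raises(ConfigurationError):
        cluster_permutation_test(np.ones((4, 3)), n_permutations=50)


# ------------------------------------------------------------------- accuracy

def test_accuracy_is_perfect_for_normative_reports(prob_seqs, prob_norms):
    traces = [EstimateTrace(np.concatenate([[0.5], n.v]), subject_id="a0",
                            sequence_id=s.sequence_id)
              for s, n in zip(prob_seqs, prob_norms)]
    acc = estimate_accuracy(traces, prob_norms, n_bins=6)
    assert acc.mean_r == pytest.approx(1.0, abs=1e-12)
    assert len(acc.bin_normative) == 6
    np.testing.assert_allclose(acc.bin_subject, acc.bin_normative, atol=1e-12)


def test_accuracy_degrades_with_report_noise(prob_seqs, prob_norms):
    def mean_r(noise):
        traces = [EstimateTrace(np.concatenate([[0.5], v]), subject_id=f"a{s}",
                                sequence_id=seq.sequence_id)
                  for s in range(4)
                  for seq, n in zip(prob_seqs, prob_norms)
                  for v in [np.clip(
                      n.v + np.random.default_rng(
                          1000 * s + hash(seq.sequence_id) % 997
                      ).normal(0, noise, len(n.v)), 0, 1)]]
        norms = [n for _ in range(4) for n in prob_norms]
        return estimate_accuracy(traces, norms).mean_r

    rs = [mean_r(n) for n in (0.02, 0.1, 0.25)]
    assert rs[0] > rs[1] > rs[2]
    assert rs[0] < 1.0


# ------------------------------------------------------------ update counting

def test_update_frequency_statistics():
    every = _trace(np.linspace(0.2, 0.8, 11))
    s = update_frequency_stats([every])
    assert s.fraction_single == 1.0 and s.mean_interval == 1.0

    alternating = _trace([0.5, 0.5, 0.6, 0.6, 0.7, 0.7, 0.8])
    s2 = update_frequency_stats([alternating])
    assert s2.fraction_single == 0.0
    assert s2.mean_interval == pytest.approx(2.0)

    frozen = _trace([0.5] * 10)
    s3 = update_frequency_stats([frozen])
    assert s3.n_updates == 0 and np.isnan(s3.fraction_single)


def test_dynamics_survive_dropping_nonupdated_observations(mag_seqs):
    """Restricting to observations with an overt update preserves the
    qualitative pattern (peak at the first post-change observation)."""
    traces = simulate_cohort(mag_seqs, 6, AgentConfig(kind="normative"), seed=2)
    by_id = {s.sequence_id: s for s in mag_seqs}
    tseqs = [by_id[t.sequence_id] for t in traces]
    series = []
    for t, s in zip(traces, tseqs):
        ser = compute_learning_rates(t, s)
        moved = np.abs(np.diff(t.v)) > 1e-6
        ser.excluded = ser.excluded | ~moved
        ser.alpha = np.where(ser.excluded, np.nan, ser.alpha)
        series.append(ser)
    dyn = align_to_changepoints(series, tseqs)
    assert dyn.offsets[np.nanargmax(dyn.mean_curve)] == 1
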