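"""Observation-level learning rates and change-point-aligned dynamics.

The apparent learning rate ``alpha_t = (v_t - v_{t-1}) / (x_t - v_{t-1})``
is measured directly from an estimate trace, without fitting a model.  The
dynamics analysis aligns these learning rates to change points, averages
within subject, and tests post-change offsets against a pre-change baseline
with a sign-flip cluster permutation test that controls the family-wise
error rate across offsets.

Offset convention: the first observation generated after a change point is
offset +1; the two observations immediately before the change are offsets
-1 and -2 (the baseline).  There is no offset 0.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .agents import EstimateTrace
from .errors import ConfigurationError, DataError
from .normative import NormativeTrace, apparent_learning_rate
from .seqgen import ObservationSequence

__all__ = [
    "LearningRateSeries",
    "DynamicsResult",
    "Cluster",
    "AccuracyResult",
    "UpdateStats",
    "MAGNITUDE_ALPHA_BOUNDS",
    "compute_learning_rates",
    "align_to_changepoints",
    "cluster_permutation_test",
    "changepoint_dynamics",
    "estimate_accuracy",
    "update_frequency_stats",
]

logger = logging.getLogger(__name__)

#: magnitude-task learning rates outside these bounds are treated as outliers
#: (they arise when the prediction error is very close to zero)
MAGNITUDE_ALPHA_BOUNDS = (-0.6, 1.3)

#: minimum |v_t - v_{t-1}| counting as an overt update of the report
UPDATE_THRESHOLD = 1e-6

_ZERO_PE_EPS = 1e-12


@dataclass
class LearningRateSeries:
    """Per-observation learning rates for one (subject, sequence) pair.

    ``alpha`` is NaN wherever ``excluded`` is True (zero prediction error or
    magnitude-task outlier).
    """

    alpha: np.ndarray
    excluded: np.ndarray
    subject_id: str = ""
    sequence_id: str = ""
    task: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.alpha)

    def valid_mask(self) -> np.ndarray:
        return ~self.excluded


@dataclass
class Cluster:
    """A contiguous run of offsets from the cluster permutation test."""

    offsets: Tuple[int, ...]
    stat: float
    p_value: float
    significant: bool


@dataclass
class DynamicsResult:
    """Change-point-aligned learning-rate dynamics across subjects."""

    offsets: np.ndarray
    mean_curve: np.ndarray
    sem_curve: np.ndarray
    baseline: float
    subject_curves: np.ndarray  # n_subjects x n_offsets
    subject_baselines: np.ndarray
    subject_ids: List[str]
    clusters: List[Cluster] = field(default_factory=list)


@dataclass
class AccuracyResult:
    """Subject-vs-normative estimate accuracy (correlation + calibration)."""

    subject_ids: List[str]
    per_subject_r: np.ndarray
    mean_r: float
    sem_r: float
    bin_normative: np.ndarray  # mean normative estimate per quantile bin
    bin_subject: np.ndarray    # mean subject estimate per quantile bin
    n_undefined: int = 0


@dataclass
class UpdateStats:
    """How often the report is overtly updated."""

    fraction_single: float  # fraction of updates occurring after 1 observation
    mean_interval: float    # mean observations per update
    n_updates: int
    n_obs: int


def compute_learning_rates(
    trace: EstimateTrace,
    seq: ObservationSequence,
    exclude_outliers: bool = True,
) -> LearningRateSeries:
    """Measure per-observation learning rates of a trace on its sequence.

    Zero-prediction-error observations are excluded (undefined ratio).  For
    the magnitude task, learning rates outside ``MAGNITUDE_ALPHA_BOUNDS``
    are additionally excluded when ``exclude_outliers`` is set.
    """
    if trace.n_obs != seq.n_obs:
        raise DataError(
            f"trace has {trace.n_obs} observations but sequence has {seq.n_obs}")
    alpha = apparent_learning_rate(trace.estimates, seq.x, v0=trace.v[0],
                                   eps=_ZERO_PE_EPS)
    excluded = np.isnan(alpha)
    if exclude_outliers and seq.task == "magnitude":
        lo, hi = MAGNITUDE_ALPHA_BOUNDS
        with np.errstate(invalid="ignore"):
            excluded |= (alpha < lo) | (alpha > hi)
    alpha = np.where(excluded, np.nan, alpha)
    return LearningRateSeries(alpha, excluded, subject_id=trace.subject_id,
                              sequence_id=trace.sequence_id, task=seq.task)


def _window_offsets(window: Tuple[int, int]) -> np.ndarray:
    pre, post = window
    if pre > -2:
        raise ConfigurationError("window must include at least 2 pre-change offsets")
    return np.array([o for o in range(pre, post + 1) if o != 0])


def _offset_to_index(cp_index: int, offset: int) -> int:
    # offset +1 is the change-point observation itself (first of new regime)
    return cp_index + offset - 1 if offset > 0 else cp_index + offset


def align_to_changepoints(
    series: Sequence[LearningRateSeries],
    seqs: Sequence[ObservationSequence],
    window: Tuple[int, int] = (-2, 8),
) -> DynamicsResult:
    """Average learning rates around change points, within then across subjects.

    For each subject, alpha is averaged at each offset across all change
    points of all their sessions (excluded observations skipped; change
    points with fewer than two clean pre-change observations dropped).  The
    baseline is the mean over offsets -2 and -1.  Subjects without any valid
    aligned data are dropped with a warning.
    """
    if len(series) != len(seqs):
        raise DataError("series and seqs must be parallel lists")
    offsets = _window_offsets(window)
    per_subject: Dict[str, List[List[float]]] = {}
    for ser, seq in zip(series, seqs):
        store = per_subject.setdefault(ser.subject_id,
                                       [[] for _ in range(len(offsets))])
        for c in seq.changepoint_indices():
            if c < 2:  # needs two clean pre-change observations
                continue
            for k, o in enumerate(offsets):
                i = _offset_to_index(c, int(o))
                if 0 <= i < ser.n_obs and not ser.excluded[i]:
                    store[k].append(float(ser.alpha[i]))

    ids, curves, baselines = [], [], []
    base_cols = [k for k, o in enumerate(offsets) if o in (-2, -1)]
    for sid, store in per_subject.items():
        curve = np.array([np.mean(vals) if vals else np.nan for vals in store])
        base = np.nanmean(curve[base_cols]) if np.any(
            np.isfinite(curve[base_cols])) else np.nan
        if not np.any(np.isfinite(curve)):
            logger.warning("subject %s has no valid change-point-aligned data; "
                           "dropped", sid)
            continue
        ids.append(sid)
        curves.append(curve)
        baselines.append(base)

    if not ids:
        raise DataError("no subject has valid change-point-aligned data")
    curves = np.vstack(curves)
    baselines = np.asarray(baselines)
    mean_curve = np.nanmean(curves, axis=0)
    n_eff = np.sum(np.isfinite(curves), axis=0)
    sem_curve = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return DynamicsResult(offsets, mean_curve, sem_curve,
                          float(np.nanmean(baselines)), curves, baselines,
                          ids)


def _cluster_stats(t_vals: np.ndarray, p_vals: np.ndarray,
                   alpha_level: float) -> List[Tuple[slice, float]]:
    """Contiguous runs of below-threshold offsets, scored by summed |t|."""
    below = p_vals < alpha_level
    clusters = []
    start = None
    for i, b in enumerate(list(below) + [False]):
        if b and start is None:
            start = i
        elif not b and start is not None:
            sl = slice(start, i)
            clusters.append((sl, float(np.abs(t_vals[sl]).sum())))
            start = None
    return clusters


#: mean differences below this (in learning-rate units) are treated as zero;
#: guards against float rounding in exactly-constant curves (delta-rule agents)
_NULL_EPS = 1e-9


def _t_one_sample(d: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column-wise one-sample t statistics and two-tailed p-values."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(sd == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    t = np.where(np.abs(mean) < _NULL_EPS, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return t, p


def cluster_permutation_test(
    diffs: np.ndarray,
    alpha_level: float = 0.05,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> List[Cluster]:
    """FWE-corrected cluster test of per-subject difference curves against 0.

    ``diffs`` is an (n_subjects, n_offsets) matrix, typically offset values
    minus the subject's pre-change baseline.  Offsets where a two-tailed
    one-sample t-test gives ``p < alpha_level`` form contiguous clusters
    scored by summed |t|.  The null distribution of the maximum cluster
    statistic is built by randomly sign-flipping whole subject curves; when
    ``2**n_subjects <= n_permutations`` all sign patterns are enumerated,
    making the p-values exact.
    """
    if n_permutations < 100:
        raise ConfigurationError(
            f"n_permutations must be >= 100, got {n_permutations}")
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 2 or diffs.shape[0] < 2:
        raise DataError("need a 2-D matrix with at least 2 subjects")
    if not np.all(np.isfinite(diffs)):
        raise DataError("difference curves must be finite (drop NaN subjects first)")
    n, m = diffs.shape

    t_obs, p_obs = _t_one_sample(diffs)
    observed = _cluster_stats(t_obs, p_obs, alpha_level)
    if not observed:
        return []

    exact = 2 ** n <= n_permutations
    if exact:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_permutations, n))

    # vectorized sign-flip t-stats: sum of squares is flip-invariant
    ss = (diffs ** 2).sum(axis=0)                       # (m,)
    means = signs @ diffs / n                           # (P, m)
    var = (ss - n * means ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = means / np.sqrt(var / n)
    t_null = np.where(var <= 0, np.where(means == 0, 0.0,
                                         np.inf * np.sign(means)), t_null)
    t_null = np.where(np.abs(means) < _NULL_EPS, 0.0, t_null)
    p_null = 2.0 * stats.t.sf(np.abs(t_null), n - 1)

    max_stat = np.zeros(signs.shape[0])
    for j in range(signs.shape[0]):
        cl = _cluster_stats(t_null[j], p_null[j], alpha_level)
        if cl:
            max_stat[j] = max(s for _, s in cl)

    clusters = []
    for sl, stat in observed:
        if exact:
            p = float(np.mean(max_stat >= stat - 1e-12))
        else:
            p = float((1 + np.sum(max_stat >= stat - 1e-12))
                      / (1 + n_permutations))
        clusters.append(Cluster(tuple(range(sl.start, sl.stop)), stat, p,
                                p < alpha_level))
    return clusters


def changepoint_dynamics(
    series: Sequence[LearningRateSeries],
    seqs: Sequence[ObservationSequence],
    window: Tuple[int, int] = (-2, 8),
    alpha_level: float = 0.05,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> DynamicsResult:
    """Align, average and cluster-test learning rates around change points.

    The cluster test is run on the post-change offsets (baseline subtracted
    per subject); subjects with incomplete curves are excluded from the test
    (but kept in the mean curve).  Cluster offsets are reported in
    change-point-relative units.
    """
    result = align_to_changepoints(series, seqs, window)
    post_cols = np.flatnonzero(result.offsets > 0)
    diffs = result.subject_curves[:, post_cols] - result.subject_baselines[:, None]
    ok = np.all(np.isfinite(diffs), axis=1)
    if ok.sum() >= 2:
        raw = cluster_permutation_test(diffs[ok], alpha_level=alpha_level,
                                       n_permutations=n_permutations, seed=seed)
        post_offsets = result.offsets[post_cols]
        result.clusters = [
            Cluster(tuple(int(post_offsets[i]) for i in c.offsets),
                    c.stat, c.p_value, c.significant)
            for c in raw
        ]
    return result


def estimate_accuracy(
    traces: Sequence[EstimateTrace],
    normative_traces: Sequence[NormativeTrace],
    n_bins: int = 6,
) -> AccuracyResult:
    """Compare subject estimates with normative estimates.

    Computes the per-subject Pearson correlation (pooled over the subject's
    sessions) plus a calibration curve: subject estimates averaged within
    quantile bins of the normative estimate (per subject, then across
    subjects).  Subjects with constant estimates have undefined correlation
    and are excluded from the group statistics (counted in
    ``n_undefined``).
    """
    if len(traces) != len(normative_traces):
        raise DataError("traces and normative_traces must be parallel lists")
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")
    by_subject: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
    for tr, nt in zip(traces, normative_traces):
        if tr.n_obs != nt.n_obs:
            raise DataError("trace and normative trace lengths differ")
        by_subject.setdefault(tr.subject_id, []).append((tr.estimates, nt.v))

    ids, rs = [], []
    bin_sub = np.zeros((0, n_bins))
    bin_norm = np.zeros((0, n_bins))
    n_undefined = 0
    for sid, pairs in by_subject.items():
        vs = np.concatenate([p[0] for p in pairs])
        vn = np.concatenate([p[1] for p in pairs])
        if np.std(vs) == 0 or np.std(vn) == 0:
            n_undefined += 1
            continue
        r = stats.pearsonr(vs, vn).statistic
        ids.append(sid)
        rs.append(r)
        edges = np.quantile(vn, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges[1:-1], vn, side="right"), 0, n_bins - 1)
        bs = np.array([vs[idx == b].mean() if np.any(idx == b) else np.nan
                       for b in range(n_bins)])
        bn = np.array([vn[idx == b].mean() if np.any(idx == b) else np.nan
                       for b in range(n_bins)])
        bin_sub = np.vstack([bin_sub, bs])
        bin_norm = np.vstack([bin_norm, bn])

    if not ids:
        raise DataError("no subject with defined correlation")
    rs = np.asarray(rs)
    return AccuracyResult(ids, rs, float(np.mean(rs)),
                          float(np.std(rs, ddof=1) / np.sqrt(len(rs)))
                          if len(rs) > 1 else 0.0,
                          np.nanmean(bin_norm, axis=0),
                          np.nanmean(bin_sub, axis=0),
                          n_undefined=n_undefined)


def update_frequency_stats(
    traces: Sequence[EstimateTrace],
    threshold: float = UPDATE_THRESHOLD,
) -> UpdateStats:
    """Statistics of overt report updates pooled across traces.

    An update is any report change larger than ``threshold``.  Intervals
    are counted between consecutive updates within a session (the interval
    to the first update counts from the session start).  Returns the
    fraction of updates occurring after exactly one observation and the
    mean observations-per-update; NaN when no updates occur.
    """
    intervals: List[int] = []
    n_obs = 0
    for tr in traces:
        n_obs += tr.n_obs
        moved = np.abs(np.diff(tr.v)) > threshold
        times = np.flatnonzero(moved) + 1  # 1-based observation index
        if times.size:
            intervals.extend(np.diff(np.concatenate([[0], times])).tolist())
    if not intervals:
        return UpdateStats(float("nan"), float("nan"), 0, n_obs)
    intervals_arr = np.asarray(intervals)
    return UpdateStats(float(np.mean(intervals_arr == 1)),
                       float(np.mean(intervals_arr)),
                       len(intervals), n_obs)
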