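"""Two-determinant regression of the learning rate.

Normative theory identifies two quantities that jointly determine how much
an observation should update the estimate: the change-point probability
``Omega_t`` (how much the observation suggests the world just changed) and
the prior uncertainty ``u_t`` (how uncertain the belief already was).  To
compare their influence on the measured learning rate, all three variables
are z-scored within subject and the learning rate is regressed on the two
determinants by ordinary least squares; the standardized weights are then
compared across subjects at the group level.

Observations at t=1 (where the "previous posterior" is the initial prior)
and excluded learning rates are dropped before z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, DegenerateInputError
from .metrics import LearningRateSeries
from .normative import NormativeTrace

__all__ = [
    "RegressionWeights",
    "InteractionGrid",
    "regress_determinants",
    "cohort_weights",
    "group_level_tests",
    "interaction_pattern",
]

_MIN_OBS = 10


@dataclass
class RegressionWeights:
    """Standardized regression weights of one subject."""

    w_omega: float
    w_u: float
    intercept: float
    n_obs: int
    subject_id: str = ""
    task: str = ""


@dataclass
class InteractionGrid:
    """Mean learning rate per (Omega-quantile, u-quantile) cell."""

    cell_means: np.ndarray       # n_omega_bins x n_u_bins, NaN where empty
    cell_counts: np.ndarray
    n_omega_bins: int
    n_u_bins: int
    subject_grids: np.ndarray    # n_subjects x n_omega_bins x n_u_bins


def _as_list(obj):
    return list(obj) if isinstance(obj, (list, tuple)) else [obj]


def _pooled_arrays(series, traces) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool (alpha, omega, u) over sessions, keeping valid, t>1 observations."""
    a_parts, o_parts, u_parts = [], [], []
    for ser, tr in zip(_as_list(series), _as_list(traces)):
        if ser.n_obs != tr.n_obs:
            raise DataError("series and trace lengths differ")
        keep = ser.valid_mask()
        keep[0] = False  # t=1 has no well-defined prior context
        a_parts.append(ser.alpha[keep])
        o_parts.append(tr.omega[keep])
        u_parts.append(tr.u[keep])
    return (np.concatenate(a_parts), np.concatenate(o_parts),
            np.concatenate(u_parts))


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = np.std(x)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise DegenerateInputError(f"regressor {name!r} is constant")
    return (x - np.mean(x)) / sd


def regress_determinants(series, traces, subject_id: str = "",
                         task: str = "") -> RegressionWeights:
    """OLS of z-scored learning rate on z-scored Omega and u for one subject.

    ``series``/``traces`` may be single objects or parallel lists of a
    subject's sessions; observations are pooled across sessions before
    z-scoring (maximizing the per-subject sample).
    """
    alpha, omega, u = _pooled_arrays(series, traces)
    if len(alpha) < _MIN_OBS:
        raise DataError(
            f"need >= {_MIN_OBS} valid observations, got {len(alpha)}")
    za, zo, zu = (_zscore(alpha, "alpha"), _zscore(omega, "omega"),
                  _zscore(u, "u"))
    X = sm.add_constant(np.column_stack([zo, zu]))
    fit = sm.OLS(za, X).fit()
    ser0 = _as_list(series)[0]
    return RegressionWeights(float(fit.params[1]), float(fit.params[2]),
                             float(fit.params[0]), len(alpha),
                             subject_id=subject_id or ser0.subject_id,
                             task=task or ser0.task)


def _group_by_subject(series, traces) -> Dict[str, Tuple[list, list]]:
    groups: Dict[str, Tuple[list, list]] = {}
    for ser, tr in zip(series, traces):
        s, t = groups.setdefault(ser.subject_id, ([], []))
        s.append(ser)
        t.append(tr)
    return groups


def cohort_weights(series: Sequence[LearningRateSeries],
                   traces: Sequence[NormativeTrace]) -> List[RegressionWeights]:
    """Per-subject regression weights for a whole cohort (parallel lists)."""
    if len(series) != len(traces):
        raise DataError("series and traces must be parallel lists")
    return [regress_determinants(s, t, subject_id=sid)
            for sid, (s, t) in _group_by_subject(series, traces).items()]


def group_level_tests(weights: Sequence[RegressionWeights]) -> dict:
    """Group-level t-tests on the standardized weights.

    Two-tailed one-sample t-tests of each weight against zero, plus a paired
    t-test of w_omega vs. w_u (positive t means Omega dominates).
    """
    if len(weights) < 2:
        raise DataError("need >= 2 subjects")
    wo = np.array([w.w_omega for w in weights])
    wu = np.array([w.w_u for w in weights])
    n = len(weights)

    def _summary(x, res):
        return {"mean": float(np.mean(x)),
                "sem": float(np.std(x, ddof=1) / np.sqrt(n)),
                "t": float(res.statistic), "df": n - 1,
                "p": float(res.pvalue)}

    return {
        "n_subjects": n,
        "omega_vs_zero": _summary(wo, stats.ttest_1samp(wo, 0.0)),
        "u_vs_zero": _summary(wu, stats.ttest_1samp(wu, 0.0)),
        "omega_vs_u_paired": _summary(wo - wu, stats.ttest_rel(wo, wu)),
    }


def interaction_pattern(
    series: Sequence[LearningRateSeries],
    traces: Sequence[NormativeTrace],
    n_omega_bins: int = 2,
    n_u_bins: int = 4,
) -> InteractionGrid:
    """Joint effect of the two determinants on the learning rate.

    For each subject, Omega and u are split into quantile bins (computed on
    that subject's own retained observations) and the mean learning rate is
    taken per cell; cells are then averaged across subjects.  Empty cells
    are NaN, not errors.
    """
    if n_omega_bins < 2 or n_u_bins < 2:
        raise DataError("need >= 2 bins per determinant")
    groups = _group_by_subject(series, traces)
    grids = np.full((len(groups), n_omega_bins, n_u_bins), np.nan)
    counts = np.zeros((n_omega_bins, n_u_bins), dtype=int)
    for s_i, (sid, (sers, trs)) in enumerate(groups.items()):
        alpha, omega, u = _pooled_arrays(sers, trs)
        if len(alpha) < max(n_omega_bins, n_u_bins):
            continue
        oi = _quantile_bin(omega, n_omega_bins)
        ui = _quantile_bin(u, n_u_bins)
        for a in range(n_omega_bins):
            for b in range(n_u_bins):
                sel = (oi == a) & (ui == b)
                if np.any(sel):
                    grids[s_i, a, b] = alpha[sel].mean()
                    counts[a, b] += int(sel.sum())
    cell_means = np.nanmean(grids, axis=0)
    return InteractionGrid(cell_means, counts, n_omega_bins, n_u_bins, grids)


def _quantile_bin(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    return np.clip(np.searchsorted(edges[1:-1], x, side="right"), 0, n_bins - 1)
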