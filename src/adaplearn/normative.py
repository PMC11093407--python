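"""Normative Bayesian observers for the two tasks.

Both observers track the posterior over the hidden quantity under the true
generative model (known hazard rate and observation noise) and expose, per
observation, the three quantities the behavioral analyses rest on:

* ``v_t`` -- posterior-mean estimate after observation ``x_t``;
* ``u_t`` -- *prior uncertainty*, the SD of the belief distribution before
  ``x_t`` is incorporated;
* ``omega_t`` -- *change-point probability*, the posterior probability that
  a change occurred at the latest observation,

      Omega_t = p(x_t | change) * H / p(x_t | x_{1:t-1}),

  which is inversely related to the overlap of prior and likelihood;
* ``alpha_t`` -- the apparent learning rate obtained by applying
  ``alpha_t = (v_t - v_{t-1}) / (x_t - v_{t-1})`` to the observer's own
  estimates, with ``v_0 = 0.5`` (slider starts centered).

Probability task
----------------
Exact Bayesian filtering on a grid over the hidden Bernoulli parameter:
predict (mix the previous posterior with the uniform change prior by the
hazard) then update (multiply by the Bernoulli likelihood, renormalize).
The filter assumes a constant hazard and uniform resampling on the support,
ignoring the generative refractory period and odds constraint, i.e. the
slightly mismatched but standard observer model for this task family.

Magnitude task
--------------
The reduced Gaussian change-point model, which propagates only the mean
``b_t`` and the relative uncertainty ``tau_t`` of the posterior instead of
the full run-length distribution:

    Omega_t = U(x_t) H / (U(x_t) H + N(x_t; b_t, sigma_t^2) (1 - H))
    sigma_t^2 = N^2 + tau_t N^2 / (1 - tau_t)
    eta_t = tau_t + (1 - tau_t) Omega_t
    b_{t+1} = b_t + eta_t (x_t - b_t)
    u_t^2 = tau_t sigma_t^2

with the ``tau`` recursion given in :func:`run_magnitude_model`.  ``U`` is
the uniform density (1 on the unit slider range), ``N`` the generative
observation SD, ``H`` the hazard.

Caveat: the quantities at t=1 are computed from the initial prior standing
in for a "previous posterior"; analyses should (and in this package do)
exclude the first observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataError
from .seqgen import ObservationSequence

__all__ = [
    "ProbabilityFilterConfig",
    "MagnitudeModelConfig",
    "PosteriorGrid",
    "NormativeTrace",
    "run_probability_filter",
    "run_magnitude_model",
    "run_observer",
    "measure_determinant_correlation",
    "apparent_learning_rate",
]

_V0 = 0.5  # slider starts centered; estimate before any observation


@dataclass(frozen=True)
class ProbabilityFilterConfig:
    """Observer model for the probability task.

    ``hazard`` is the assumed per-observation change probability,
    ``p_support`` the interval of the hidden probability, and ``grid_size``
    the number of equally spaced grid points discretizing it (301 makes the
    discretization error far below behavioral effect sizes; halving or
    doubling it does not change any reported statistic meaningfully).
    """

    hazard: float = 1.0 / 20.0
    p_support: Tuple[float, float] = (0.1, 0.9)
    grid_size: int = 301

    def validate(self) -> None:
        if self.grid_size < 3:
            raise ConfigurationError(f"grid_size must be >= 3, got {self.grid_size}")
        if not 0.0 <= self.hazard <= 1.0:
            raise ConfigurationError(f"hazard must be in [0, 1], got {self.hazard}")
        lo, hi = self.p_support
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                f"p_support must lie strictly inside (0, 1), got {self.p_support}"
            )


@dataclass(frozen=True)
class MagnitudeModelConfig:
    """Observer model for the magnitude task (reduced Gaussian model).

    ``obs_sd`` is N, the generative observation SD the observer assumes;
    ``hazard`` is H.  ``b0``/``tau0`` initialize the estimate and relative
    uncertainty (the slider starts at 0.5; tau0=0.5 encodes moderate initial
    uncertainty).  ``tau_clip`` keeps tau away from the endpoints where
    sigma^2 would diverge or collapse.
    """

    obs_sd: float = 10.0 / 300.0
    hazard: float = 1.0 / 10.0
    x_support: Tuple[float, float] = (0.0, 1.0)
    b0: float = 0.5
    tau0: float = 0.5
    tau_clip: float = 1e-6

    def validate(self) -> None:
        if self.obs_sd <= 0:
            raise ConfigurationError(f"obs_sd must be > 0, got {self.obs_sd}")
        if not 0.0 < self.hazard < 1.0:
            raise ConfigurationError(f"hazard must be in (0, 1), got {self.hazard}")
        if not 0.0 <= self.tau0 <= 1.0:
            raise ConfigurationError(f"tau0 must be in [0, 1], got {self.tau0}")


@dataclass
class PosteriorGrid:
    """Discrete belief distribution over the hidden probability."""

    grid: np.ndarray
    mass: np.ndarray

    def mean(self) -> float:
        return float(self.grid @ self.mass)

    def sd(self) -> float:
        m = self.mean()
        return float(math.sqrt(max((self.grid - m) ** 2 @ self.mass, 0.0)))


@dataclass
class NormativeTrace:
    """Per-observation outputs of a normative observer.

    ``u`` is the SD of the change-point-predicted prior (the distribution
    actually multiplied with the likelihood); ``u_prev`` is the SD of the
    previous posterior, before hazard mixing.  ``eta`` is the internal
    learning rate of the reduced magnitude model (equal to ``alpha``
    wherever the latter is defined); None for the probability filter.
    """

    task: str
    v: np.ndarray
    u: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    u_prev: np.ndarray | None = None
    eta: np.ndarray | None = None
    sequence_id: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.v)


def apparent_learning_rate(v: np.ndarray, x: np.ndarray, v0: float = _V0,
                           eps: float = 1e-12) -> np.ndarray:
    """Per-observation apparent learning rate of an estimate trace.

    ``alpha_t = (v_t - v_{t-1}) / (x_t - v_{t-1})`` with ``v_{0} = v0``.
    Observations with a near-zero prediction error (undefined ratio) are
    returned as NaN.
    """
    v_prev = np.concatenate([[v0], v[:-1]])
    denom = x - v_prev
    alpha = np.full(len(x), np.nan)
    ok = np.abs(denom) > eps
    alpha[ok] = (v[ok] - v_prev[ok]) / denom[ok]
    return alpha


def run_probability_filter(
    seq: ObservationSequence,
    config: ProbabilityFilterConfig | None = None,
) -> NormativeTrace:
    """Run grid-based Bayesian filtering on a probability-task sequence.

    Each step mixes the previous posterior with the uniform change prior
    (weight = hazard), records the prior uncertainty, multiplies by the
    Bernoulli likelihood ``h^x (1-h)^(1-x)`` and renormalizes.  The
    change-point probability divides the hazard-weighted evidence under the
    change prior by the total predictive evidence.
    """
    if config is None:
        config = ProbabilityFilterConfig()
    config.validate()
    if seq.task != "probability":
        raise DataError(f"expected a probability-task sequence, got {seq.task!r}")
    x = np.asarray(seq.x, dtype=float)
    if not np.all((x == 0.0) | (x == 1.0)):
        raise DataError("probability-task observations must be binary 0/1")

    lo, hi = config.p_support
    grid = np.linspace(lo, hi, config.grid_size)
    uniform = np.full(config.grid_size, 1.0 / config.grid_size)
    H = config.hazard

    T = len(x)
    v = np.empty(T)
    u = np.empty(T)
    u_prev = np.empty(T)
    omega = np.empty(T)

    post = uniform.copy()
    for t in range(T):
        lik = grid if x[t] == 1.0 else 1.0 - grid
        prior = (1.0 - H) * post + H * uniform
        pg_prior = PosteriorGrid(grid, prior)
        pg_post = PosteriorGrid(grid, post)
        u[t] = pg_prior.sd()
        u_prev[t] = pg_post.sd()
        evid_change = float(lik @ uniform)
        evid = float(lik @ prior)
        omega[t] = H * evid_change / evid
        post = lik * prior / evid
        post /= post.sum()  # guard drift; evid already normalizes in exact math
        v[t] = float(grid @ post)

    alpha = apparent_learning_rate(v, x)
    return NormativeTrace("probability", v, u, omega, alpha, u_prev=u_prev,
                          sequence_id=seq.sequence_id)


def run_magnitude_model(
    seq: ObservationSequence,
    config: MagnitudeModelConfig | None = None,
) -> NormativeTrace:
    """Run the reduced Gaussian change-point model on a magnitude sequence.

    Iterates the two-moment recursion documented in the module docstring;
    the relative-uncertainty update is

        A = N^2 Omega_t + (1 - Omega_t) tau_t N^2
            + Omega_t (1 - Omega_t) (x_t tau_t + b_t (1 - tau_t) - x_t)^2
        tau_{t+1} = A / (A + N^2)

    ``tau`` is clamped to ``[tau_clip, 1 - tau_clip]`` to keep the
    predictive variance finite.
    """
    if config is None:
        config = MagnitudeModelConfig()
    config.validate()
    if seq.task != "magnitude":
        raise DataError(f"expected a magnitude-task sequence, got {seq.task!r}")
    x = np.asarray(seq.x, dtype=float)

    N2 = config.obs_sd ** 2
    H = config.hazard
    x_lo, x_hi = config.x_support
    u_density = 1.0 / (x_hi - x_lo)  # uniform change likelihood, 1 on [0, 1]

    T = len(x)
    v = np.empty(T)
    u = np.empty(T)
    omega = np.empty(T)
    eta = np.empty(T)

    b = config.b0
    tau = min(max(config.tau0, config.tau_clip), 1.0 - config.tau_clip)
    for t in range(T):
        sigma2 = N2 + tau * N2 / (1.0 - tau)
        u[t] = math.sqrt(tau * sigma2)
        gauss = math.exp(-0.5 * (x[t] - b) ** 2 / sigma2) / math.sqrt(
            2.0 * math.pi * sigma2)
        om = u_density * H / (u_density * H + gauss * (1.0 - H))
        et = tau + (1.0 - tau) * om
        b_new = b + et * (x[t] - b)
        a_num = (N2 * om + (1.0 - om) * tau * N2
                 + om * (1.0 - om) * (x[t] * tau + b * (1.0 - tau) - x[t]) ** 2)
        tau = a_num / (a_num + N2)
        tau = min(max(tau, config.tau_clip), 1.0 - config.tau_clip)
        omega[t] = om
        eta[t] = et
        v[t] = b_new
        b = b_new

    alpha = apparent_learning_rate(v, x, v0=config.b0)
    return NormativeTrace("magnitude", v, u, omega, alpha, u_prev=u.copy(),
                          eta=eta, sequence_id=seq.sequence_id)


def run_observer(seq: ObservationSequence, config=None) -> NormativeTrace:
    """Dispatch to the task-appropriate observer.

    When ``config`` is None the observer parameters are taken from the
    sequence's generative config (the observer knows the true process),
    falling back to the task defaults.
    """
    if seq.task == "magnitude":
        if config is None and seq.config is not None:
            config = MagnitudeModelConfig(obs_sd=seq.config.noise_sd,
                                          hazard=seq.config.hazard)
        return run_magnitude_model(seq, config)
    if seq.task == "probability":
        if config is None and seq.config is not None:
            config = ProbabilityFilterConfig(hazard=seq.config.hazard,
                                             p_support=tuple(seq.config.p_support))
        return run_probability_filter(seq, config)
    raise DataError(f"unknown task {seq.task!r}")


def measure_determinant_correlation(
    traces: Sequence[NormativeTrace],
    seqs: Sequence[ObservationSequence],
) -> float:
    """Spearman correlation between Omega_t and |x_t - v_{t-1}| pooled over
    all observations of all sequences (excluding t=1, whose "previous
    posterior" is the initial prior)."""
    if len(traces) == 0 or len(traces) != len(seqs):
        raise DataError("need equally many (non-empty) traces and sequences")
    omegas, abs_pe = [], []
    for tr, seq in zip(traces, seqs):
        if tr.n_obs != seq.n_obs:
            raise DataError("trace and sequence lengths differ")
        v_prev = np.concatenate([[_V0], tr.v[:-1]])
        omegas.append(tr.omega[1:])
        abs_pe.append(np.abs(seq.x - v_prev)[1:])
    rho = stats.spearmanr(np.concatenate(omegas), np.concatenate(abs_pe)).statistic
    return float(rho)
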