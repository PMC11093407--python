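"""Generative processes for the magnitude and probability estimation tasks.

Both tasks present a sequence of observations drawn from a hidden quantity
that changes abruptly at unpredictable *change points*:

* **Magnitude task** -- observations are horizontal positions in normalized
  screen units, Gaussian around a hidden mean (SD 10/300).  The mean is
  redrawn uniformly at each change point.  Change points occur with hazard
  1/10 per observation, except during a 3-observation refractory period
  after each change.
* **Probability task** -- observations are binary colors (0 = yellow,
  1 = blue), Bernoulli with a hidden probability drawn uniformly on
  [0.1, 0.9].  Hazard is 1/20 with a 6-observation refractory period, and
  every change must move the odds p/(1-p) at least fourfold so that changes
  are in principle detectable.

All values live in normalized slider units on [0, 1].  Sequences are fully
determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "MagnitudeGenConfig",
    "ProbabilityGenConfig",
    "ObservationSequence",
    "generate_magnitude_sequence",
    "generate_probability_sequence",
    "generate_sequence_set",
    "derive_seeds",
]

#: iteration cap for the odds-constraint rejection sampler
_MAX_REJECTION_ITER = 10_000


@dataclass(frozen=True)
class MagnitudeGenConfig:
    """Generative parameters of the magnitude task.

    Parameters
    ----------
    noise_sd : float
        Standard deviation of observations around the hidden mean, in
        normalized slider units (task value 10/300).
    hazard : float
        Per-observation change-point probability outside the refractory
        period (task value 1/10).
    refractory : int
        Number of observations after a change point during which the hazard
        is zero (task value 3).
    n_obs : int
        Observations per session (task value 75).
    mean_support : tuple of float
        Interval from which the hidden mean is drawn.  The original interval
        is not documented; ``[0.1, 0.9]`` keeps Gaussian observations almost
        surely on-screen and mirrors the probability task.
    """

    noise_sd: float = 10.0 / 300.0
    hazard: float = 1.0 / 10.0
    refractory: int = 3
    n_obs: int = 75
    mean_support: Tuple[float, float] = (0.1, 0.9)

    def validate(self) -> None:
        if not 0.0 < self.noise_sd < 1.0:
            raise ConfigurationError(f"noise_sd must be in (0, 1), got {self.noise_sd}")
        if not 0.0 <= self.hazard <= 1.0:
            raise ConfigurationError(f"hazard must be in [0, 1], got {self.hazard}")
        if self.refractory < 0:
            raise ConfigurationError(f"refractory must be >= 0, got {self.refractory}")
        if self.n_obs < 1:
            raise ConfigurationError(f"n_obs must be >= 1, got {self.n_obs}")
        lo, hi = self.mean_support
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigurationError(
                f"mean_support must be a sub-interval of [0, 1], got {self.mean_support}"
            )


@dataclass(frozen=True)
class ProbabilityGenConfig:
    """Generative parameters of the probability task.

    Parameters
    ----------
    hazard : float
        Per-observation change-point probability (task value 1/20).
    refractory : int
        Zero-hazard observations after a change point (task value 6).
    n_obs : int
        Observations per session (task value 75).
    p_support : tuple of float
        Interval of the hidden Bernoulli parameter (task value [0.1, 0.9]).
    min_odds_factor : float
        Minimum multiplicative change of the odds p/(1-p) at a change point
        (task value 4); enforced by rejection sampling.
    """

    hazard: float = 1.0 / 20.0
    refractory: int = 6
    n_obs: int = 75
    p_support: Tuple[float, float] = (0.1, 0.9)
    min_odds_factor: float = 4.0

    def validate(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ConfigurationError(f"hazard must be in [0, 1], got {self.hazard}")
        if self.refractory < 0:
            raise ConfigurationError(f"refractory must be >= 0, got {self.refractory}")
        if self.n_obs < 1:
            raise ConfigurationError(f"n_obs must be >= 1, got {self.n_obs}")
        lo, hi = self.p_support
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                f"p_support must lie strictly inside (0, 1), got {self.p_support}"
            )
        if self.min_odds_factor < 1.0:
            raise ConfigurationError(
                f"min_odds_factor must be >= 1, got {self.min_odds_factor}"
            )


@dataclass
class ObservationSequence:
    """One session's observations plus the hidden generative ground truth.

    Attributes
    ----------
    task : str
        ``"magnitude"`` or ``"probability"``.
    x : ndarray
        Observations in [0, 1]; binary for the probability task.
    h : ndarray
        Hidden generative quantity per observation (mean or Bernoulli p),
        piecewise constant between change points.
    cp : ndarray of bool
        True at the first observation generated after a change (``h[t] !=
        h[t-1]``).  The initial draw at t=1 is flagged as a change point and
        counts for refractory accounting.
    """

    task: str
    x: np.ndarray
    h: np.ndarray
    cp: np.ndarray
    seed: int | None = None
    sequence_id: str = ""
    config: object = None

    @property
    def n_obs(self) -> int:
        return len(self.x)

    def changepoint_indices(self, include_start: bool = False) -> np.ndarray:
        """0-based indices of change points, by default excluding t=1."""
        idx = np.flatnonzero(self.cp)
        if not include_start:
            idx = idx[idx > 0]
        return idx


def _draw_changepoints(rng: np.random.Generator, n_obs: int, hazard: float,
                       refractory: int) -> np.ndarray:
    """Sample change-point flags with a refractory hazard schedule.

    The hazard is zero for ``refractory`` observations following each change
    point (the sequence start counts as one), and ``hazard`` thereafter.
    """
    cp = np.zeros(n_obs, dtype=bool)
    cp[0] = True
    last_change = 0
    for t in range(1, n_obs):
        if t - last_change > refractory and rng.random() < hazard:
            cp[t] = True
            last_change = t
    return cp


def generate_magnitude_sequence(
    config: MagnitudeGenConfig, seed: int, sequence_id: str = ""
) -> ObservationSequence:
    """Generate one magnitude-task session.

    The hidden mean is drawn uniformly from ``config.mean_support`` at t=1
    and redrawn at each change point; observations are Gaussian around it
    and clipped to the slider range [0, 1].
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cp = _draw_changepoints(rng, config.n_obs, config.hazard, config.refractory)
    lo, hi = config.mean_support
    h = np.empty(config.n_obs)
    cur = np.nan
    for t in range(config.n_obs):
        if cp[t]:
            cur = rng.uniform(lo, hi)
        h[t] = cur
    x = np.clip(rng.normal(h, config.noise_sd), 0.0, 1.0)
    return ObservationSequence("magnitude", x, h, cp, seed=seed,
                               sequence_id=sequence_id, config=config)


def _resample_odds_constrained(
    rng: np.random.Generator, p_old: float, config: ProbabilityGenConfig
) -> float:
    """Redraw p uniformly on the support until the odds change >= the factor."""
    odds_old = p_old / (1.0 - p_old)
    f = config.min_odds_factor
    lo, hi = config.p_support
    for _ in range(_MAX_REJECTION_ITER):
        p_new = rng.uniform(lo, hi)
        ratio = (p_new / (1.0 - p_new)) / odds_old
        if ratio >= f or ratio <= 1.0 / f:
            return p_new
    raise ConfigurationError(
        "min_odds_factor leaves (almost) no admissible values in p_support "
        f"(no draw accepted in {_MAX_REJECTION_ITER} attempts from p={p_old})"
    )


def generate_probability_sequence(
    config: ProbabilityGenConfig, seed: int, sequence_id: str = ""
) -> ObservationSequence:
    """Generate one probability-task session.

    The hidden probability starts uniform on ``config.p_support`` and is
    resampled at each change point subject to the minimum odds-change
    constraint; observations are Bernoulli draws coded 0/1.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cp = _draw_changepoints(rng, config.n_obs, config.hazard, config.refractory)
    lo, hi = config.p_support
    h = np.empty(config.n_obs)
    cur = np.nan
    for t in range(config.n_obs):
        if cp[t]:
            cur = rng.uniform(lo, hi) if t == 0 else _resample_odds_constrained(
                rng, cur, config)
        h[t] = cur
    x = (rng.random(config.n_obs) < h).astype(float)
    return ObservationSequence("probability", x, h, cp, seed=seed,
                               sequence_id=sequence_id, config=config)


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministically derive ``n`` child seeds from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n, np.uint32)


def generate_sequence_set(
    config: MagnitudeGenConfig | ProbabilityGenConfig,
    n_sequences: int,
    seed: int,
    id_prefix: str | None = None,
) -> List[ObservationSequence]:
    """Generate ``n_sequences`` independent sessions from a master seed.

    Per-sequence seeds are derived deterministically with
    :func:`derive_seeds`, so the set is reproducible and element ``i``
    equals a direct call with the i-th derived seed.
    """
    if n_sequences < 1:
        raise ConfigurationError(f"n_sequences must be >= 1, got {n_sequences}")
    gen = (generate_magnitude_sequence
           if isinstance(config, MagnitudeGenConfig)
           else generate_probability_sequence)
    task = "mag" if isinstance(config, MagnitudeGenConfig) else "prob"
    prefix = id_prefix if id_prefix is not None else task
    seeds = derive_seeds(seed, n_sequences)
    return [gen(config, int(s), sequence_id=f"{prefix}{i:03d}")
            for i, s in enumerate(seeds)]
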