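"""Simulated learners standing in for human subjects.

Five agent kinds cover the control models used in the analyses:

* ``delta_rule`` -- fixed learning rate: ``v_t = v_{t-1} + alpha (x_t - v_{t-1})``.
* ``normative`` -- reports the normative observer's posterior mean.
* ``report_noise`` -- normative estimate plus i.i.d. Gaussian report noise.
* ``learning_noise_constant`` -- delta-rule learner whose update is
  corrupted by Gaussian noise of constant SD (learning noise).
* ``learning_noise_scaled`` -- same, with the noise SD proportional to the
  magnitude of the prediction error.

The learning-noise agents are the control for the question of whether mere
variability in the learning process can masquerade as adaptive learning-rate
dynamics; their base learner is deliberately non-adaptive (fixed rate).

Reports are clipped to the slider range [0, 1] and start at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .normative import NormativeTrace, run_observer
from .seqgen import ObservationSequence, derive_seeds

__all__ = ["AgentConfig", "EstimateTrace", "simulate_agent", "simulate_cohort"]

_KINDS = ("delta_rule", "normative", "report_noise",
          "learning_noise_constant", "learning_noise_scaled")

_V0 = 0.5


@dataclass(frozen=True)
class AgentConfig:
    """Agent kind plus its (kind-specific) parameters.

    ``alpha`` is the fixed learning rate of the delta-rule and
    learning-noise agents; ``noise_sd`` the SD of the noise term in
    normalized slider units (for the scaled variant, the SD per unit of
    |prediction error|).
    """

    kind: str = "normative"
    alpha: float = 0.1
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown agent kind {self.kind!r}; expected one of {_KINDS}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.noise_sd < 0.0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class EstimateTrace:
    """Reports ``v_0..v_T`` of one agent (or subject) for one session.

    ``v[0] = 0.5`` (slider starts centered); ``v[t]`` is the report after
    observation ``x_t``.
    """

    v: np.ndarray
    subject_id: str = ""
    sequence_id: str = ""
    kind: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.v) - 1

    @property
    def estimates(self) -> np.ndarray:
        """Per-observation reports ``v_1..v_T`` (drops the initial 0.5)."""
        return self.v[1:]


def simulate_agent(
    seq: ObservationSequence,
    config: AgentConfig,
    normative_trace: Optional[NormativeTrace] = None,
    subject_id: str = "",
) -> EstimateTrace:
    """Simulate one agent on one sequence; deterministic under the config seed.

    The normative trace is computed from the sequence when needed and not
    supplied (pass it explicitly to amortize across agents sharing
    sequences).
    """
    config.validate()
    x = np.asarray(seq.x, dtype=float)
    T = len(x)
    v = np.empty(T + 1)
    v[0] = _V0
    rng = np.random.default_rng(config.seed)

    # Noisy reports are truncated to the admissible estimate range: in the
    # probability task the hidden probability (hence any sensible report)
    # lies within p_support, and letting noise push reports to the slider
    # edge would create near-zero prediction errors -- and thus divergent
    # measured learning rates -- that real reports cannot produce.
    # Deterministic agents never need this and keep the full slider range.
    if seq.task == "probability" and config.kind != "delta_rule":
        lo, hi = (seq.config.p_support if seq.config is not None
                  else (0.1, 0.9))
    else:
        lo, hi = 0.0, 1.0

    if config.kind in ("normative", "report_noise"):
        if normative_trace is None:
            normative_trace = run_observer(seq)
        v[1:] = normative_trace.v
        if config.kind == "report_noise" and config.noise_sd > 0:
            v[1:] = v[1:] + rng.normal(0.0, config.noise_sd, T)
        np.clip(v[1:], lo, hi, out=v[1:])
    elif config.kind == "delta_rule":
        for t in range(T):
            v[t + 1] = v[t] + config.alpha * (x[t] - v[t])
    else:  # learning-noise agents: fixed-rate update + noise in the update
        eps = rng.normal(0.0, 1.0, T)
        for t in range(T):
            pe = x[t] - v[t]
            sd = (config.noise_sd if config.kind == "learning_noise_constant"
                  else config.noise_sd * abs(pe))
            v[t + 1] = min(max(v[t] + config.alpha * pe + sd * eps[t], lo), hi)

    np.clip(v, 0.0, 1.0, out=v)
    return EstimateTrace(v, subject_id=subject_id,
                         sequence_id=seq.sequence_id, kind=config.kind)


def simulate_cohort(
    seqs: Sequence[ObservationSequence],
    n_agents: int,
    config: AgentConfig,
    seed: int,
    n_sessions: Optional[int] = None,
) -> List[EstimateTrace]:
    """Simulate a cohort where each agent sees a random subset of sequences.

    Each agent is assigned ``n_sessions`` sequences sampled without
    replacement from the set (all of them by default), emulating how
    sessions were drawn from shared sequence pools, so multiple agents see
    the same sequence -- the structure the group-level decomposition needs.
    Agent noise seeds are derived from ``seed``; identical seeds give an
    identical cohort.
    """
    if n_agents < 1:
        raise ConfigurationError(f"n_agents must be >= 1, got {n_agents}")
    if n_sessions is None:
        n_sessions = len(seqs)
    if not 1 <= n_sessions <= len(seqs):
        raise ConfigurationError(
            f"n_sessions must be in [1, {len(seqs)}], got {n_sessions}")

    rng = np.random.default_rng(seed)
    agent_seeds = derive_seeds(seed, n_agents)
    norm_cache: Dict[int, NormativeTrace] = {}
    traces: List[EstimateTrace] = []
    for i in range(n_agents):
        chosen = rng.choice(len(seqs), size=n_sessions, replace=False)
        session_seeds = derive_seeds(int(agent_seeds[i]), n_sessions)
        for k, j in enumerate(chosen):
            cfg = replace(config, seed=int(session_seeds[k]))
            if j not in norm_cache and cfg.kind in ("normative", "report_noise"):
                norm_cache[j] = run_observer(seqs[j])
            traces.append(simulate_agent(seqs[j], cfg,
                                         normative_trace=norm_cache.get(j),
                                         subject_id=f"agent{i:03d}"))
    return traces
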