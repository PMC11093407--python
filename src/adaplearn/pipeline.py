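"""End-to-end analysis pipeline: generate -> simulate -> analyze -> report.

``run_pipeline`` chains the package stages for both tasks under one master
seed and writes tidy CSVs plus a JSON summary.  Every derived seed and
parameter is logged in the summary, and two runs with the same config and
seed produce byte-identical output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import agents, decomposition, determinants, io, metrics, normative, seqgen
from .errors import StageError

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "tasks": {
        "magnitude": {"n_sequences": 100, "n_sessions": 6},
        "probability": {"n_sequences": 150, "n_sessions": 15},
    },
    # subject-like cohort: normative estimates with report noise at the
    # human deviation scale
    "cohort": {"n_agents": 24, "kind": "report_noise", "alpha": 0.1,
               "noise_sd": 0.03},
    "analyses": ["spearman", "dynamics", "determinants", "decompose",
                 "accuracy"],
    "options": {"n_permutations": 1000, "n_boot": 1000, "n_bins": 6,
                "alpha_level": 0.05},
}


def load_config(path) -> dict:
    """Load a YAML/JSON config file, filling unset keys from the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULT_CONFIG, raw)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(
            base.get(k), dict) else v
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None  # NaN/inf are not valid JSON
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _gen_config(task: str, overrides: dict):
    cls = (seqgen.MagnitudeGenConfig if task == "magnitude"
           else seqgen.ProbabilityGenConfig)
    fields = {k: v for k, v in overrides.items()
              if k in cls.__dataclass_fields__}
    return cls(**fields)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: Optional[dict] = None,
                 outdir: Optional[str] = None) -> dict:
    """Run the full pipeline; returns (and optionally writes) the summary.

    Stages per task: sequence generation, normative observers, cohort
    simulation, then the requested analyses (Spearman determinant check,
    change-point dynamics, two-determinant regression, bias/variance
    decomposition, estimate accuracy).  A stage failure raises
    :class:`~adaplearn.errors.StageError` naming the stage; outputs written
    before the failure are retained.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    opts = cfg["options"]
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # one derived seed per (task, purpose), all below 2**32
    task_names = sorted(cfg["tasks"])
    seeds = seqgen.derive_seeds(seed, 4 * len(task_names))
    summary: dict = {"config": _jsonable(cfg), "tasks": {}}

    for i, task in enumerate(task_names):
        tcfg = cfg["tasks"][task]
        s_gen, s_cohort, s_perm, s_boot = (int(s) for s in seeds[4 * i:4 * i + 4])
        tsum: dict = {"seeds": {"generate": s_gen, "cohort": s_cohort,
                                "permutation": s_perm, "bootstrap": s_boot}}

        seqs = _stage("generate")(seqgen.generate_sequence_set)(
            _gen_config(task, tcfg), int(tcfg["n_sequences"]), s_gen)
        seqs_by_id = {s.sequence_id: s for s in seqs}
        norm_by_id = _stage("normative")(
            lambda: {s.sequence_id: normative.run_observer(s) for s in seqs})()

        cohort_cfg = agents.AgentConfig(kind=cfg["cohort"]["kind"],
                                        alpha=float(cfg["cohort"]["alpha"]),
                                        noise_sd=float(cfg["cohort"]["noise_sd"]))
        traces = _stage("simulate")(agents.simulate_cohort)(
            seqs, int(cfg["cohort"]["n_agents"]), cohort_cfg, s_cohort,
            n_sessions=min(int(tcfg["n_sessions"]), len(seqs)))
        trace_seqs = [seqs_by_id[tr.sequence_id] for tr in traces]
        series = [metrics.compute_learning_rates(tr, sq)
                  for tr, sq in zip(traces, trace_seqs)]
        trace_norms = [norm_by_id[tr.sequence_id] for tr in traces]

        if out:
            io.write_sequences(seqs, out / f"sequences_{task}.csv")
            io.write_normative_traces(list(norm_by_id.values()),
                                      out / f"normative_{task}.csv")
            io.write_sessions(io.session_table_from_traces(traces, seqs_by_id),
                              out / f"sessions_{task}.csv")

        analyses = cfg["analyses"]
        if "spearman" in analyses:
            rho = _stage("spearman")(normative.measure_determinant_correlation)(
                list(norm_by_id.values()), [seqs_by_id[k] for k in norm_by_id])
            tsum["spearman_omega_abs_pe"] = rho
        if "dynamics" in analyses:
            dyn = _stage("dynamics")(metrics.changepoint_dynamics)(
                series, trace_seqs, alpha_level=float(opts["alpha_level"]),
                n_permutations=int(opts["n_permutations"]), seed=s_perm)
            tsum["dynamics"] = {
                "offsets": dyn.offsets, "mean_curve": dyn.mean_curve,
                "sem_curve": dyn.sem_curve, "baseline": dyn.baseline,
                "clusters": [{"offsets": c.offsets, "stat": c.stat,
                              "p": c.p_value, "significant": c.significant}
                             for c in dyn.clusters],
            }
            if out:
                pd.DataFrame({"offset": dyn.offsets, "mean": dyn.mean_curve,
                              "sem": dyn.sem_curve}).to_csv(
                    out / f"dynamics_{task}.csv", index=False)
        if "determinants" in analyses:
            weights = _stage("determinants")(determinants.cohort_weights)(
                series, trace_norms)
            tests = determinants.group_level_tests(weights)
            tsum["determinants"] = {
                "w_omega_mean": tests["omega_vs_zero"]["mean"],
                "w_u_mean": tests["u_vs_zero"]["mean"],
                "tests": tests,
            }
            if out:
                pd.DataFrame([{"subject_id": w.subject_id, "task": task,
                               "w_omega": w.w_omega, "w_u": w.w_u,
                               "intercept": w.intercept, "n_obs": w.n_obs}
                              for w in weights]).to_csv(
                    out / f"weights_{task}.csv", index=False)
        if "decompose" in analyses:
            dec = _stage("decompose")(decomposition.decompose_mse)(
                traces, norm_by_id)
            decomposition.bootstrap_se(dec, n_boot=int(opts["n_boot"]),
                                       seed=s_boot)
            tsum["decomposition"] = {
                "prop_bias": dec.prop_bias, "prop_var": dec.prop_var,
                "se_bias": dec.se_bias, "se_var": dec.se_var,
            }
            if out:
                dec.per_cell.to_csv(out / f"decomposition_{task}.csv",
                                    index=False)
        if "accuracy" in analyses:
            acc = _stage("accuracy")(metrics.estimate_accuracy)(
                traces, trace_norms, n_bins=int(opts["n_bins"]))
            tsum["accuracy"] = {"mean_r": acc.mean_r, "sem_r": acc.sem_r,
                                "bin_normative": acc.bin_normative,
                                "bin_subject": acc.bin_subject}

        summary["tasks"][task] = tsum

    summary = _jsonable(summary)
    if out:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
    return summary
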