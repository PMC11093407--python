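"""Group-level bias/variance decomposition of deviations from normative
estimates.

When several subjects see the *same* observation sequence, their estimates
for a given observation can be compared to the normative estimate and the
mean squared error split into a systematic and a non-systematic part.  For
sequence ``k`` and observation ``t`` with ``N(k)`` subject estimates
``v^s(i)`` and normative estimate ``v^n``:

    mse = (1/N) sum_i (v^n - v^s(i))^2
    sbe = (v^n - mean_i v^s(i))^2          (squared bias error, systematic)
    var = (1/N) sum_i (mean_i v^s - v^s(i))^2   (variance error)

and ``mse = sbe + var`` exactly.  Per-cell values are summed across
observations and sequences (unweighted by N(k) by default), and the bias
and variance proportions of the total are reported as percentages, with
standard errors obtained by bootstrapping over sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import EstimateTrace
from .errors import ConfigurationError, DataError
from .normative import NormativeTrace

__all__ = ["DecompositionResult", "decompose_mse", "bootstrap_se"]

logger = logging.getLogger(__name__)


@dataclass
class DecompositionResult:
    """Per-cell and total bias/variance decomposition.

    ``per_cell`` has one row per (sequence, observation) cell with >= 2
    subject estimates; ``per_sequence`` sums cells within each sequence
    (the bootstrap resampling unit).  Proportions are percentages of the
    total mse and sum to 100.
    """

    per_cell: pd.DataFrame
    per_sequence: pd.DataFrame
    total_mse: float
    total_sbe: float
    total_var: float
    prop_bias: float
    prop_var: float
    se_bias: Optional[float] = None
    se_var: Optional[float] = None
    n_skipped_cells: int = 0


def decompose_mse(
    traces: Sequence[EstimateTrace],
    normative_traces: Mapping[str, NormativeTrace],
    weight_by_n: bool = False,
) -> DecompositionResult:
    """Decompose subject-vs-normative mse into bias and variance errors.

    ``traces`` are grouped by ``sequence_id``; ``normative_traces`` maps
    sequence id to the normative trace of that sequence.  Cells with fewer
    than two subject estimates are skipped (counted, logged).  With
    ``weight_by_n`` the per-cell values are weighted by the number of
    subjects when totalling (default: unweighted sums).
    """
    by_seq: Dict[str, List[EstimateTrace]] = {}
    for tr in traces:
        by_seq.setdefault(tr.sequence_id, []).append(tr)

    rows = []
    n_skipped = 0
    for sid, group in sorted(by_seq.items()):
        if sid not in normative_traces:
            raise DataError(f"no normative trace for sequence {sid!r}")
        vn = normative_traces[sid].v
        mat = np.vstack([tr.estimates for tr in group])  # n_subj x T
        if mat.shape[1] != len(vn):
            raise DataError(f"length mismatch for sequence {sid!r}")
        n = mat.shape[0]
        if n < 2:
            n_skipped += mat.shape[1]
            continue
        mean_v = mat.mean(axis=0)
        mse = ((vn[None, :] - mat) ** 2).mean(axis=0)
        sbe = (vn - mean_v) ** 2
        var = ((mean_v[None, :] - mat) ** 2).mean(axis=0)
        for t in range(mat.shape[1]):
            rows.append((sid, t + 1, n, mse[t], sbe[t], var[t]))
    if n_skipped:
        logger.info("skipped %d cells with < 2 subject estimates", n_skipped)
    if not rows:
        raise DataError("no (sequence, observation) cell has >= 2 estimates")

    per_cell = pd.DataFrame(rows, columns=["sequence_id", "t", "n_subjects",
                                           "mse", "sbe", "var"])
    w = per_cell["n_subjects"] if weight_by_n else 1.0
    weighted = per_cell[["mse", "sbe", "var"]].multiply(w, axis=0)
    per_sequence = weighted.groupby(per_cell["sequence_id"]).sum().reset_index()

    tot = weighted.sum()
    if tot["mse"] == 0.0:  # perfectly normative cohort: proportions undefined
        prop_bias = prop_var = float("nan")
    else:
        prop_bias = 100.0 * tot["sbe"] / tot["mse"]
        prop_var = 100.0 * tot["var"] / tot["mse"]
    return DecompositionResult(per_cell, per_sequence,
                               float(tot["mse"]), float(tot["sbe"]),
                               float(tot["var"]), float(prop_bias),
                               float(prop_var), n_skipped_cells=n_skipped)


def bootstrap_se(
    result: DecompositionResult,
    n_boot: int = 10_000,
    seed: int = 0,
) -> DecompositionResult:
    """Bootstrap standard errors of the bias/variance proportions.

    Sequences (not subjects) are resampled with replacement ``n_boot``
    times; the proportions are recomputed per resample and the SE is their
    standard deviation across resamples.  Fills ``se_bias``/``se_var`` in
    place and returns the result for chaining; deterministic under
    ``seed``.
    """
    if n_boot < 100:
        raise ConfigurationError(f"n_boot must be >= 100, got {n_boot}")
    rng = np.random.default_rng(seed)
    totals = result.per_sequence[["mse", "sbe", "var"]].to_numpy()
    K = totals.shape[0]
    idx = rng.integers(0, K, size=(n_boot, K))
    boot = totals[idx].sum(axis=1)  # n_boot x 3
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_bias = 100.0 * boot[:, 1] / boot[:, 0]
        prop_var = 100.0 * boot[:, 2] / boot[:, 0]
    result.se_bias = float(np.std(prop_bias))
    result.se_var = float(np.std(prop_var))
    return result
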