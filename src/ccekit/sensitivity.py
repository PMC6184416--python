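"""Garson connection-weight sensitivity analysis with random restarts.

A trained single-hidden-layer perceptron encodes the input-output relation
in its connection weights.  Garson's algorithm attributes the output to
input i through the hidden layer:

    Q_i = sum_h ( |W_ih| / sum_k |W_kh| ) * |v_h|
          -----------------------------------------
          sum_j sum_h ( |W_jh| / sum_k |W_kh| ) * |v_h|

where W is the input->hidden weight matrix and v the hidden->output
vector; biases are excluded (the classical formulation).  The resulting
importances are nonnegative and sum to one.

A single fit's importances depend on the random weight initialization, so
the pipeline averages Garson importances over many independently
re-initialized trained networks (random restarts) and checks convergence
of the running mean across restart-count checkpoints (e.g. 100 / 500 /
1000 / 2000).  One-hot dummy columns are summed back to their source
factor before ranking, which preserves the sum-to-one contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann_model import FittedPerceptron, NetworkSpec, PerceptronWeights, fit
from .errors import ConfigError, FitError, UndefinedMetricError
from .preprocessing import ModelMatrix, SplitPlan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityResult:
    """Restart-averaged factor importances.

    ``importances`` sums to 1; ``ranking`` sorts descending with
    lexicographic factor-name tie-break; ``per_restart`` holds one row per
    successful restart.
    """

    importances: dict[str, float]
    n_restarts: int
    ranking: tuple[str, ...]
    per_restart: pd.DataFrame | None = None
    n_failures: int = 0
    max_drift: float = float("nan")


def garson(weights: PerceptronWeights) -> np.ndarray:
    """Per-encoded-column Garson importance vector (sums to 1).

    Hidden nodes whose input weights are all zero are skipped; if every
    weight is zero the importance is undefined.
    """
    W = np.abs(weights.W)
    v = np.abs(weights.v)
    col_sums = W.sum(axis=0)
    active = col_sums > 0
    if not active.any() or not np.any(v[active] * col_sums[active]):
        raise UndefinedMetricError("all connection weights are zero; importance undefined")
    contrib = (W[:, active] / col_sums[active]) @ v[active]
    total = contrib.sum()
    if total == 0:
        raise UndefinedMetricError("zero total contribution; importance undefined")
    return contrib / total


def aggregate_to_factors(
    column_importances: np.ndarray,
    columns: list[str],
    feature_map: dict[str, str],
) -> dict[str, float]:
    """Sum encoded-column importances back to their source factors."""
    if len(column_importances) != len(columns):
        raise ConfigError("importance vector length does not match columns")
    out: dict[str, float] = {}
    for value, name in zip(column_importances, columns):
        if name not in feature_map:
            raise ConfigError(f"encoded column {name!r} missing from feature_map")
        factor = feature_map[name]
        out[factor] = out.get(factor, 0.0) + float(value)
    return out


def rank_factors(importances: dict[str, float]) -> tuple[str, ...]:
    """Factors sorted by descending importance; ties break
    lexicographically by name."""
    return tuple(sorted(importances, key=lambda f: (-importances[f], f)))


def model_importances(model: FittedPerceptron) -> dict[str, float]:
    """Garson importances of one fitted network, aggregated to factors."""
    return aggregate_to_factors(garson(model.weights), model.columns, model.feature_map)


def restart_sensitivity(
    matrix: ModelMatrix,
    spec: NetworkSpec,
    n_restarts: int,
    base_seed: int = 0,
    split: SplitPlan | None = None,
    keep_per_restart: bool = True,
) -> SensitivityResult:
    """Average Garson importances over ``n_restarts`` independently
    initialized fits (seeds ``base_seed .. base_seed+n_restarts-1``).

    Individual fit failures are logged and skipped; more than 10% failures
    abort the run.
    """
    if n_restarts < 1:
        raise ConfigError(f"n_restarts must be >= 1, got {n_restarts}")
    rows = []
    factors: list[str] | None = None
    failures = 0
    for r in range(n_restarts):
        seed = base_seed + r
        try:
            model = fit(matrix, NetworkSpec(
                n_hidden=spec.n_hidden,
                l2_alpha=spec.l2_alpha,
                max_iter=spec.max_iter,
                seed=seed,
            ), split)
            imp = model_importances(model)
        except (FitError, UndefinedMetricError) as exc:
            failures += 1
            logger.warning("restart %d (seed %d) failed: %s", r, seed, exc)
            continue
        if factors is None:
            factors = list(imp)
        rows.append([imp[f] for f in factors])
    if failures > 0.1 * n_restarts or not rows:
        raise FitError(f"{failures}/{n_restarts} restarts failed")
    per_restart = pd.DataFrame(rows, columns=factors)
    mean = per_restart.mean(axis=0)
    importances = {f: float(mean[f]) for f in per_restart.columns}
    return SensitivityResult(
        importances=importances,
        n_restarts=len(rows),
        ranking=rank_factors(importances),
        per_restart=per_restart if keep_per_restart else None,
        n_failures=failures,
    )


def checkpoint_sensitivity(
    matrix: ModelMatrix,
    spec: NetworkSpec,
    checkpoints: tuple[int, ...] = (100, 500, 1000, 2000),
    base_seed: int = 0,
    split: SplitPlan | None = None,
) -> list[SensitivityResult]:
    """Restart-averaged importances at increasing restart counts, sharing
    one seed stream (the mean at checkpoint c uses restarts 0..c-1)."""
    if any(b >= a for b, a in zip(checkpoints, checkpoints[1:])) or len(checkpoints) < 2:
        raise ConfigError("checkpoints must be strictly increasing, >= 2 of them")
    full = restart_sensitivity(
        matrix, spec, max(checkpoints), base_seed, split, keep_per_restart=True
    )
    results = []
    for c in checkpoints:
        head = full.per_restart.iloc[:c]
        mean = head.mean(axis=0)
        importances = {f: float(mean[f]) for f in head.columns}
        results.append(
            SensitivityResult(
                importances=importances,
                n_restarts=len(head),
                ranking=rank_factors(importances),
                per_restart=None,
            )
        )
    return results


def convergence_report(
    results: list[SensitivityResult], threshold: float = 0.01
) -> pd.DataFrame:
    """Tabulate importances by restart count with checkpoint-to-checkpoint
    drift.

    ``max_drift`` at checkpoint t is ``max_f |Q_f(t) - Q_f(t-1)|``;
    convergence is flagged when it falls below ``threshold`` (default 0.01,
    of the order of the 3rd decimal at which published restart-averaged
    indices stabilize).
    """
    if len(results) < 2:
        raise ConfigError("need at least two checkpoints")
    counts = [r.n_restarts for r in results]
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ConfigError(f"checkpoints must be strictly increasing, got {counts}")
    factors = list(results[0].importances)
    rows = []
    prev = None
    for res in results:
        row = {"n_restarts": res.n_restarts}
        row.update({f: res.importances[f] for f in factors})
        if prev is None:
            row["max_drift"] = float("nan")
            row["converged"] = False
        else:
            drift = max(abs(res.importances[f] - prev[f]) for f in factors)
            row["max_drift"] = drift
            row["converged"] = drift < threshold
        prev = res.importances
        rows.append(row)
    return pd.DataFrame(rows)
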