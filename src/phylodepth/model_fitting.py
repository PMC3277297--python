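"""Grid-search fit of the evolvability-model parameter p to an empirical
binned depth curve.

For each candidate p the model's depth curve is rebuilt from scratch:
simulate ``replicates`` trees, pool the (A, d) points of *all* their
subtrees (the same convention used when the empirical cloud is built), bin
with the empirical curve's binning parameters, and score the curve-to-curve
distance on the overlapping bins.  The argmin over the grid is the fitted
p, with ties broken toward the smaller p.

The default objective is the root-mean-square difference of binned mean
depths (fully specified and deterministic given the two curves); an
inverse-variance-weighted variant (weights 1 / pooled se^2) is available
behind ``weighted=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scaling_analysis import BinnedCurve, compare_curves, log_bin
from .simulators import evolvability_subtree_points

__all__ = ["FitResult", "error_objective", "fit_p", "DEFAULT_GRID"]

#: p values scanned by default: 0.21 .. 0.27 in steps of 0.01.
DEFAULT_GRID = tuple(round(0.21 + 0.01 * i, 2) for i in range(7))


@dataclass
class FitResult:
    """Grid of (p, error, error_se) plus the argmin.

    ``error_se`` is a Monte-Carlo uncertainty on the error value, from
    splitting the replicates into 5 batches.  Identical (seed, grid,
    replicates, generations) inputs reproduce the result bit for bit.
    """

    grid: pd.DataFrame
    p_best: float
    replicates: int
    generations: int
    seed: int
    weighted: bool = False


def error_objective(
    model_curve: BinnedCurve, empirical: BinnedCurve, weighted: bool = False
) -> float:
    """Distance between two identically binned curves on their common bins.

    Default: RMS of the per-bin mean-depth differences.  ``weighted=True``
    uses inverse-variance weights 1/se^2 (pooled over the two curves; bins
    where the pooled se is 0 fall back to the largest finite weight).
    Raises if the curves share no bins.
    """
    comp = compare_curves(model_curve, empirical)
    diff = comp.table["d_diff"].to_numpy(float)
    if not weighted:
        return float(np.sqrt(np.mean(diff**2)))
    se2 = comp.table["pooled_se"].to_numpy(float) ** 2
    if np.all(se2 == 0):
        return float(np.sqrt(np.mean(diff**2)))
    w = np.where(se2 > 0, 1.0 / np.where(se2 > 0, se2, 1.0), np.nan)
    w = np.where(np.isnan(w), np.nanmax(w), w)
    return float(np.sqrt(np.sum(w * diff**2) / np.sum(w)))


_N_ERROR_BATCHES = 5


def fit_p(
    empirical: BinnedCurve,
    grid=DEFAULT_GRID,
    replicates: int = 500,
    generations: int = 14,
    seed: int = 0,
    weighted: bool = False,
) -> FitResult:
    """Grid search over p minimizing the curve error to ``empirical``.

    Model curves are binned with the empirical curve's ``base`` and
    ``min_A`` (enforced, not assumed).  Requires replicates >= 10 and every
    grid value in [0, 1]; raises if a model curve shares no bins with the
    empirical one (simulate more generations in that case).
    """
    grid = sorted(float(p) for p in grid)
    if not grid:
        raise ValueError("empty p grid")
    if any(not 0.0 <= p <= 1.0 for p in grid):
        raise ValueError("grid values must lie in [0, 1]")
    if replicates < 10:
        raise ValueError(f"replicates must be >= 10, got {replicates}")
    if empirical.table.empty:
        raise ValueError("empirical curve is empty")

    rows = []
    for i, p in enumerate(grid):
        # one sub-seed per (grid index, batch): reproducible, order-free
        batch_sizes = [replicates // _N_ERROR_BATCHES] * _N_ERROR_BATCHES
        for j in range(replicates % _N_ERROR_BATCHES):
            batch_sizes[j] += 1
        batch_points = []
        batch_errors = []
        for b, size in enumerate(batch_sizes):
            if size == 0:
                continue
            pts = evolvability_subtree_points(
                p, generations, size, seed=_subseed(seed, i, b)
            )
            batch_points.append(pts)
            try:
                curve_b = log_bin(pts, base=empirical.base, min_A=empirical.min_A)
                batch_errors.append(error_objective(curve_b, empirical, weighted))
            except ValueError:
                pass  # a small batch may miss the empirical bins entirely
        A = np.concatenate([a for a, _ in batch_points])
        d = np.concatenate([d for _, d in batch_points])
        model_curve = log_bin((A, d), base=empirical.base, min_A=empirical.min_A)
        try:
            err = error_objective(model_curve, empirical, weighted)
        except ValueError as exc:
            raise ValueError(
                f"model curve at p={p} shares no bins with the empirical curve; "
                "simulate more generations"
            ) from exc
        if len(batch_errors) >= 2:
            err_se = float(np.std(batch_errors, ddof=1) / np.sqrt(len(batch_errors)))
        else:
            err_se = float("nan")
        rows.append((p, err, err_se))

    table = pd.DataFrame(rows, columns=["p", "error", "error_se"])
    # ties toward the smaller p: grid ascending + first argmin
    p_best = float(table.loc[table["error"].idxmin(), "p"])
    return FitResult(
        grid=table, p_best=p_best, replicates=replicates,
        generations=generations, seed=seed, weighted=weighted,
    )


def _subseed(seed: int, grid_index: int, batch: int) -> int:
    return int(
        np.random.SeedSequence([int(seed) % (2**31), grid_index, batch])
        .generate_state(1)[0] % (2**31)
    )
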