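"""From subtree clouds to binned depth-scaling curves, local scaling
exponents, and the tree-size power-law fit.

The central object is the :class:`BinnedCurve`: subtree (A, d) points
pooled over a tree set and averaged within logarithmic bins of A.  Points
from nested subtrees of the same tree are not statistically independent;
they are pooled anyway (each subtree contributes one point) and the
standard error is therefore a descriptive spread, not a confidence
interval.

Two candidate scaling laws for the depth curve are probed by local
(finite-difference) exponents between consecutive bins:

    eta_i  = Delta_i ln d / Delta_i ln A       (power law d ~ A^eta)
    beta_i = Delta_i ln d / Delta_i ln ln A    (d ~ (ln A)^beta)

A constant local exponent indicates the corresponding law fits.

Tree (tip-count) size distributions are fitted as a discrete power law
P(T) ~ T^-gamma by maximum likelihood with fixed lower cutoff T_min = 2,
with a log-binned least-squares alternative behind ``method="ls"``; the
complementary cumulative distribution F(T) = P(size > T) uses the strict
"greater than" convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import shape_stats
from .tree_core import Subtree, Tree, TreeNode

logger = logging.getLogger("phylodepth")

__all__ = [
    "BinnedCurve",
    "SizeDistribution",
    "CurveComparison",
    "collect_points",
    "log_bin",
    "local_exponents",
    "fit_size_distribution",
    "compare_curves",
]


@dataclass
class BinnedCurve:
    """Log-binned depth curve.

    ``table`` columns: ``k`` (bin index: the bin spans
    [min_A * base^k, min_A * base^(k+1))), ``A_center`` (geometric mean of
    the A values that fell in the bin — the mass-weighted abscissa, so a
    bin holding a single size sits exactly at that size), ``mean_d``
    (``se_d`` is sample SD / sqrt(n); 0 when a bin holds a single point),
    ``n_points``.
    """

    table: pd.DataFrame
    base: float
    min_A: int

    def to_tsv(self, path) -> None:
        """Write the curve; binning parameters go in '#' header lines so
        the file round-trips."""
        with open(path, "w") as fh:
            fh.write(f"# base={self.base!r}\n# min_A={self.min_A}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinnedCurve":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t")
        missing = {"k", "A_center", "mean_d", "se_d", "n_points"} - set(table.columns)
        if missing or "base" not in meta or "min_A" not in meta:
            raise ValueError(f"{path}: not a binned-curve TSV (missing {missing or 'header'})")
        return cls(table=table, base=float(meta["base"]), min_A=int(meta["min_A"]))

    def same_binning(self, other: "BinnedCurve") -> bool:
        return math.isclose(self.base, other.base) and self.min_A == other.min_A


def collect_points(
    tree_set: Iterable[Tree | Subtree | TreeNode] | Iterable[tuple[str, Tree]],
) -> pd.DataFrame:
    """One (A, d) point per subtree (i.e. per node) over all trees.

    Leaf points (A = 1, d = 0) are included; log-scale analyses drop them
    via ``min_A`` at the binning stage.
    """
    stats = shape_stats.stats_table(tree_set)
    return stats[["tree_id", "A", "d"]].copy()


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return points["A"].to_numpy(float), points["d"].to_numpy(float)
    A, d = points
    return np.asarray(A, dtype=float), np.asarray(d, dtype=float)


def log_bin(points, base: float = 2.0, min_A: int = 2) -> BinnedCurve:
    """Average d within logarithmic bins of A.

    Bin k spans [min_A * base^k, min_A * base^(k+1)); points with
    A < min_A are excluded; empty bins are omitted.  ``points`` is either a
    DataFrame with columns A, d or a pair of arrays.
    """
    if base <= 1:
        raise ValueError(f"bin base must be > 1, got {base}")
    A, d = _as_arrays(points)
    keep = A >= min_A
    if not keep.any():
        raise ValueError(f"no points with A >= min_A ({min_A}); nothing to bin")
    A, d = A[keep], d[keep]
    k = np.floor(np.log(A / min_A) / np.log(base)).astype(int)
    # guard against float edge effects at exact bin boundaries
    k = np.where(A >= min_A * base ** (k + 1), k + 1, k)
    k = np.where(A < min_A * base ** k.astype(float), k - 1, k)

    frame = pd.DataFrame({"k": k, "d": d, "lnA": np.log(A)})
    grouped = frame.groupby("k")
    table = grouped["d"].agg(mean_d="mean", n_points="size", sd="std").reset_index()
    table["se_d"] = np.where(
        table["n_points"] > 1, table["sd"] / np.sqrt(table["n_points"]), 0.0
    )
    n_single = int((table["n_points"] == 1).sum())
    if n_single:
        logger.warning("%d bin(s) hold a single point; their se_d is reported as 0",
                       n_single)
    table["A_center"] = np.exp(grouped["lnA"].mean().to_numpy())
    table = table[["k", "A_center", "mean_d", "se_d", "n_points"]].sort_values("k")
    return BinnedCurve(table=table.reset_index(drop=True), base=base, min_A=min_A)


def local_exponents(curve: BinnedCurve) -> pd.DataFrame:
    """Finite-difference local exponents between consecutive bins.

    Returns a DataFrame (A_center, eta, beta) with one row per consecutive
    bin pair; A_center is the geometric mean of the two bin centers.  Bins
    with mean_d <= 0 are skipped with a warning; beta is NaN where either
    bin center is <= e (ln ln undefined/degenerate).
    """
    t = curve.table
    if len(t) < 2:
        raise ValueError("need at least 2 bins to form local exponents")
    bad = t["mean_d"] <= 0
    if bad.any():
        logger.warning("skipping %d bin(s) with mean_d <= 0 in local exponents",
                       int(bad.sum()))
        t = t[~bad]
    A = t["A_center"].to_numpy(float)
    d = t["mean_d"].to_numpy(float)
    rows = []
    for i in range(len(t) - 1):
        dlnd = math.log(d[i + 1]) - math.log(d[i])
        eta = dlnd / (math.log(A[i + 1]) - math.log(A[i]))
        if A[i] > math.e and A[i + 1] > math.e:
            beta = dlnd / (math.log(math.log(A[i + 1])) - math.log(math.log(A[i])))
        else:
            logger.warning("bin pair below A = e: beta undefined, reported as NaN")
            beta = math.nan
        rows.append((math.sqrt(A[i] * A[i + 1]), eta, beta))
    return pd.DataFrame(rows, columns=["A_center", "eta", "beta"])


@dataclass
class SizeDistribution:
    """Discrete power-law fit of tree sizes (tips per tree)."""

    sizes: np.ndarray
    gamma_hat: float
    gamma_se: float
    ccdf: pd.DataFrame = field(repr=False)
    t_min: int = 2
    method: str = "mle"


def _log_zeta(gamma: float, t_min: int) -> float:
    return math.log(special.zeta(gamma, t_min))


def fit_size_distribution(
    sizes, t_min: int = 2, method: str = "mle"
) -> SizeDistribution:
    """Fit P(T) ~ T^-gamma to tree sizes with fixed lower cutoff ``t_min``.

    ``method="mle"`` (default): discrete power-law maximum likelihood,
    standard error from the observed Fisher information.  ``method="ls"``:
    least-squares slope of the log-binned empirical density — offered for
    comparability with straight-line fits, not for inference.

    Requires at least 100 sizes, all >= t_min (smaller samples are refused
    rather than silently fitted with no power) and non-degenerate support.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size < 100:
        raise ValueError(
            f"refusing to fit {sizes.size} sizes: need >= 100 for a minimally "
            "powered exponent estimate"
        )
    if (sizes < t_min).any():
        raise ValueError(f"all sizes must be >= t_min ({t_min})")
    if np.unique(sizes).size < 2:
        raise ValueError("degenerate support: all sizes equal; no exponent to fit")

    if method == "mle":
        mean_log = float(np.mean(np.log(sizes)))
        res = optimize.minimize_scalar(
            lambda g: g * mean_log + _log_zeta(g, t_min),
            bounds=(1.0001, 10.0),
            method="bounded",
        )
        gamma_hat = float(res.x)
        h = 1e-4
        curvature = (
            _log_zeta(gamma_hat + h, t_min)
            - 2 * _log_zeta(gamma_hat, t_min)
            + _log_zeta(gamma_hat - h, t_min)
        ) / h**2
        gamma_se = 1.0 / math.sqrt(sizes.size * curvature)
    elif method == "ls":
        gamma_hat, gamma_se = _ls_exponent(sizes, t_min)
    else:
        raise ValueError(f"unknown method {method!r}; expected 'mle' or 'ls'")

    # strict "greater than" CCDF at each observed size
    uniq = np.unique(sizes)
    F = np.array([(sizes > T).mean() for T in uniq])
    ccdf = pd.DataFrame({"T": uniq, "F": F})
    return SizeDistribution(
        sizes=sizes, gamma_hat=gamma_hat, gamma_se=gamma_se, ccdf=ccdf,
        t_min=t_min, method=method,
    )


def _ls_exponent(sizes: np.ndarray, t_min: int) -> tuple[float, float]:
    """Slope of log empirical density vs log size over base-2 log bins."""
    edges = [float(t_min)]
    while edges[-1] <= sizes.max():
        edges.append(edges[-1] * 2)
    counts, edges = np.histogram(sizes, bins=np.asarray(edges))
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = counts > 0
    density = counts[keep] / (widths[keep] * sizes.size)
    x = np.log(centers[keep])
    y = np.log(density)
    slope, _ = np.polyfit(x, y, 1)
    resid = y - np.polyval(np.polyfit(x, y, 1), x)
    dof = max(len(x) - 2, 1)
    se = math.sqrt(np.sum(resid**2) / dof / np.sum((x - x.mean()) ** 2))
    return float(-slope), float(se)


@dataclass
class CurveComparison:
    """Per-bin differences between two identically binned curves.

    ``table`` columns: k, A_center, d_diff (a - b), pooled_se;
    ``rms`` is the root-mean-square of d_diff over the common bins.
    """

    table: pd.DataFrame
    rms: float


def compare_curves(curve_a: BinnedCurve, curve_b: BinnedCurve) -> CurveComparison:
    """Compare two curves bin by bin; they must share binning parameters."""
    if not curve_a.same_binning(curve_b):
        raise ValueError(
            "curves were binned with different parameters "
            f"(base {curve_a.base} vs {curve_b.base}, min_A {curve_a.min_A} vs "
            f"{curve_b.min_A}); re-bin one of them"
        )
    merged = curve_a.table.merge(curve_b.table, on="k", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("curves share no bins; nothing to compare")
    table = pd.DataFrame(
        {
            "k": merged["k"],
            "A_center": merged["A_center_a"],
            "d_diff": merged["mean_d_a"] - merged["mean_d_b"],
            "pooled_se": np.sqrt(merged["se_d_a"] ** 2 + merged["se_d_b"] ** 2),
        }
    )
    rms = float(np.sqrt(np.mean(table["d_diff"] ** 2)))
    return CurveComparison(table=table, rms=rms)
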