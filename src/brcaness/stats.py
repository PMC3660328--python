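"""Classical statistics used throughout the pipeline.

Thin, explicitly-contracted wrappers around scipy/sklearn: Welch's t (with a
vectorized variant for gene ranking), two-sided Fisher's exact test
(probability-mass convention), Spearman correlation, ROC AUC
(Mann-Whitney form), balanced accuracy, and a kernel-density valley finder
for bimodal marker-gene cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


class UnimodalError(ValueError):
    """The density estimate has fewer than two modes: no valley exists."""


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance t statistic with Welch-Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("welch_t undefined: both groups have zero variance")
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return WelchResult(float(t), float(df), x.mean(), y.mean(), float(vx), float(vy))


def welch_t_matrix(values: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Row-wise Welch t (case minus control) for a genes x samples array.

    Rows with zero variance in both groups get t = 0 so they sink to the
    bottom of any |t| ranking.
    """
    values = np.asarray(values, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    x = values[:, case_mask]
    y = values[:, ~case_mask]
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("welch_t_matrix requires >= 2 samples per group")
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    diff = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t[se2 == 0.0] = 0.0
    return t


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Probability-mass convention: sum of hypergeometric probabilities of all
    tables with the same margins that are at most as probable as the observed
    one (the R ``fisher.test`` definition).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("contingency counts must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("empty contingency table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-rank tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("spearman_rho requires n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("spearman_rho undefined for a constant vector")
    return float(sps.spearmanr(x, y).statistic)


def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Return (sensitivity, specificity, balanced accuracy).

    Balanced accuracy is the mean of sensitivity and specificity, robust to
    class imbalance.
    """
    if tp + fn <= 0 or tn + fp <= 0:
        raise ValueError("both classes must be non-empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, (sens + spec) / 2.0


def roc_auc(scores, binary_labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(binary_labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def density_valley_cutoff(
    values,
    bandwidth: str | float = "silverman",
    grid_size: int = 2048,
) -> float:
    """Cutoff at the density minimum between the two largest modes.

    A Gaussian KDE is evaluated on a regular grid spanning the data (padded
    by one bandwidth); local maxima are the modes.  Raises
    :class:`UnimodalError` when fewer than two modes exist, in which case the
    caller should fall back to a supervised cutoff.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 20:
        raise ValueError("density_valley_cutoff requires n >= 20")
    kde = sps.gaussian_kde(values, bw_method=bandwidth)
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - bw, values.max() + bw, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    modes = interior[is_max]
    if len(modes) < 2:
        raise UnimodalError("density estimate is unimodal; no valley to cut at")
    top_two = modes[np.argsort(dens[modes])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])
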