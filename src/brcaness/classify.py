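"""Carrier-vs-sporadic classification by nested leave-one-out cross-validation.

For every outer fold, genes are ranked by Welch-t on the training samples
only; the number of top genes is chosen by an inner LOOCV loop (re-ranking
within each inner fold, so the held-out sample never influences selection);
a linear-kernel SVM with Platt-style probability calibration is trained and
the raw probability of the held-out sample is reweighted by the inverse
training class priors, making 0.5 a prior-free decision threshold under
class imbalance.

The lowest gene count achieving the highest mean balanced accuracy wins the
inner selection.  An intentionally leakage-enabled variant (ranking and
selection on the full data) is available as a negative control to show the
nesting is load-bearing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import _libsvm as _libsvm_backend

from .config import RunConfig
from .containers import ClassifierResult
from .stats import fisher_exact_two_sided, welch_t_matrix

logger = logging.getLogger("brcaness")

_libsvm_backend.set_verbosity_wrap(0)


# ---------------------------------------------------------------------------
# Gene ranking

def _lexical_ranks(symbols: np.ndarray) -> np.ndarray:
    """Position of each symbol in lexical order (integer tie-break key)."""
    ranks = np.empty(len(symbols), dtype=np.int64)
    ranks[np.argsort(symbols, kind="mergesort")] = np.arange(len(symbols))
    return ranks


def _rank_order(values: np.ndarray, case_mask: np.ndarray, tie_key: np.ndarray):
    """Row order by decreasing |Welch t|, ties by lexical gene symbol."""
    t = welch_t_matrix(values, case_mask)
    order = np.lexsort((tie_key, -np.abs(t)))
    return order, t


def rank_genes(expr: pd.DataFrame, case_mask) -> pd.DataFrame:
    """Rank genes by |Welch t| (case minus control) on the given samples.

    Zero-variance-in-both-groups genes get t = 0 and sink to the bottom.
    Returns a DataFrame indexed by gene with the signed ``t_statistic``.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    tie_key = _lexical_ranks(expr.index.to_numpy(dtype=str))
    order, t = _rank_order(expr.to_numpy(dtype=float), case_mask, tie_key)
    return pd.DataFrame({"t_statistic": t[order]}, index=expr.index[order])


# ---------------------------------------------------------------------------
# Linear maximum-margin classifier (libsvm backend)

class LinearSVM:
    """Soft-margin linear SVM on the low-level libsvm binding.

    Equivalent to ``sklearn.svm.SVC(kernel="linear", C=cost)`` (asserted in
    the test suite) but without the per-call validation overhead, which
    dominates when the nested cross-validation loop performs tens of
    thousands of tiny fits.  The decision function is oriented so that
    positive values point towards the case class.
    """

    def __init__(self, cost: float = 1.0):
        self.cost = float(cost)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LinearSVM":
        x = np.ascontiguousarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=bool)
        support, sv, n_sv, sv_coef, rho, *_ = _libsvm_backend.fit(
            x, y.astype(np.float64), svm_type=0, kernel="linear", C=self.cost,
            tol=1e-3,
        )
        w = (sv_coef @ sv).ravel()
        b = -float(rho[0])
        # libsvm orients the separator by internal label order (negating w,
        # keeping the offset); choose the orientation that puts cases on the
        # positive side of the training data
        dec = x @ w + b
        if dec[y].mean() < dec[~y].mean():
            w = -w
        self.w, self.b = w, b
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.w + self.b


# ---------------------------------------------------------------------------
# Probability machinery

def adjust_probability(p_raw: float, n_pos: int, n_neg: int) -> float:
    """Reweight a raw class probability by inverse training priors.

    With prior ``pi = n_pos / (n_pos + n_neg)`` the adjusted probability is
    ``(p/pi) / (p/pi + (1-p)/(1-pi))``: strictly increasing in ``p_raw``,
    identity at equal priors, and fixes 0 and 1.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both training classes must be non-empty")
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_raw must lie in [0, 1]")
    pi1 = n_pos / (n_pos + n_neg)
    pi0 = 1.0 - pi1
    num = p / pi1
    out = num / (num + (1.0 - p) / pi0)
    return float(out) if np.isscalar(p_raw) else out


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit the Platt sigmoid p = 1 / (1 + exp(A f + B)) with target smoothing.

    Newton iteration with backtracking (the standard robust formulation);
    smoothing targets (N+1)/(N+2) and 1/(N+2) prevent degenerate fits on
    separable training data.
    """
    y = np.asarray(y, dtype=bool)
    f = np.asarray(decision, dtype=float)
    prior1 = int(y.sum())
    prior0 = len(y) - prior1
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y, hi, lo)

    a, b = 0.0, np.log((prior0 + 1.0) / (prior1 + 1.0))
    min_step, sigma_tik = 1e-10, 1e-12

    def objective(a_, b_):
        z = a_ * f + b_
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    fval = objective(a, b)
    for _ in range(100):
        z = a * f + b
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))  # P(y=1 | f)
        q = 1.0 - p
        d1 = t - p
        d2 = p * q
        g1 = float(np.sum(f * d1))
        g0 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g0) < 1e-5:
            break
        h11 = float(np.sum(f * f * d2)) + sigma_tik
        h22 = float(np.sum(d2)) + sigma_tik
        h21 = float(np.sum(f * d2))
        det = h11 * h22 - h21 * h21
        da = -(h22 * g1 - h21 * g0) / det
        db = -(-h21 * g1 + h11 * g0) / det
        gd = g1 * da + g0 * db
        step = 1.0
        while step >= min_step:
            new_a, new_b = a + step * da, b + step * db
            new_f = objective(new_a, new_b)
            if new_f < fval + 1e-4 * step * gd:
                a, b, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            break
    return a, b


def _platt_prob(decision, a: float, b: float) -> np.ndarray:
    z = np.clip(a * np.asarray(decision, dtype=float) + b, -500, 500)
    return 1.0 / (1.0 + np.exp(z))


class _FoldModel:
    """Standardization + linear SVM + Platt sigmoid for one training fold."""

    def __init__(self, config: RunConfig, seed: int, calibration_cv: int):
        self.config = config
        self.seed = seed
        self.calibration_cv = calibration_cv

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_FoldModel":
        y = np.asarray(y, dtype=bool)
        self.n_pos = int(y.sum())
        self.n_neg = len(y) - self.n_pos
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("training fold lost a class")
        if self.config.standardize_genes:
            self.mean = x.mean(axis=0)
            sd = x.std(axis=0, ddof=1)
            sd[sd == 0.0] = 1.0
            self.sd = sd
            x = (x - self.mean) / self.sd
        else:
            self.mean = self.sd = None
        self.svm = LinearSVM(self.config.svm_cost).fit(x, y)

        cv = self.calibration_cv
        if cv >= 2 and min(self.n_pos, self.n_neg) >= cv:
            decision = np.empty(len(y))
            skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=self.seed)
            for tr, te in skf.split(x, y):
                sub = LinearSVM(self.config.svm_cost).fit(x[tr], y[tr])
                decision[te] = sub.decision_function(x[te])
        else:
            decision = self.svm.decision_function(x)
        self.platt_a, self.platt_b = _platt_fit(decision, y)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Imbalance-adjusted carrier probability for rows of ``x``."""
        x = np.atleast_2d(x)
        if self.mean is not None:
            x = (x - self.mean) / self.sd
        p_raw = _platt_prob(self.svm.decision_function(x), self.platt_a, self.platt_b)
        return adjust_probability(p_raw, self.n_pos, self.n_neg)


# ---------------------------------------------------------------------------
# Nested selection of the gene count

def _fold_seed(base_seed: int, fold: int) -> int:
    return (base_seed * 1_000_003 + fold * 7919 + 1) % (2**31 - 1)


def select_smallest_best(gene_counts, scores, tol: float = 1e-12) -> int:
    """The lowest gene count achieving the highest score.

    Ties (within ``tol``) go to the smaller count: prefer the most
    parsimonious signature among equally accurate ones.
    """
    gene_counts = list(gene_counts)
    scores = list(scores)
    if not gene_counts or len(gene_counts) != len(scores):
        raise ValueError("gene_counts and scores must be non-empty and aligned")
    best = max(scores)
    for g, s in sorted(zip(gene_counts, scores)):
        if s >= best - tol:
            return int(g)
    raise AssertionError("unreachable")


def inner_select_n(
    values: np.ndarray,
    case_mask: np.ndarray,
    tie_key: np.ndarray,
    config: RunConfig,
) -> int:
    """Choose the gene count by LOOCV within the training set.

    For each inner fold the genes are re-ranked on that fold's own training
    portion; for each candidate count N the held-in sample is predicted with
    the fold's top-N genes.  Returns the smallest N achieving the maximum
    mean balanced accuracy.  Inner models calibrate the Platt sigmoid on
    training decision values directly (no resampling) to keep the nested
    loop tractable.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    n = values.shape[1]
    grid = [g for g in config.gene_count_grid if g <= values.shape[0]]
    if not grid:
        raise ValueError("gene_count_grid has no entry <= gene count")
    if len(grid) == 1:
        return grid[0]

    predictions = {g: np.full(n, -1, dtype=int) for g in grid}
    usable = np.zeros(n, dtype=bool)
    max_n = grid[-1]
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        y_tr = case_mask[mask]
        if y_tr.sum() < 2 or (~y_tr).sum() < 2:
            logger.warning("inner fold %d skipped: a class has < 2 samples", j)
            continue
        usable[j] = True
        x_tr_all = values[:, mask]
        order, _ = _rank_order(x_tr_all, y_tr, tie_key)
        top = order[:max_n]
        x_tr = x_tr_all[top].T  # samples x genes
        x_te = values[top, j]
        model_cfg = config
        for g in grid:
            model = _FoldModel(model_cfg, seed=0, calibration_cv=0)
            model.fit(x_tr[:, :g], y_tr)
            p = model.predict_proba(x_te[:g])[0]
            predictions[g][j] = int(p >= config.probability_threshold)

    if not usable.any():
        raise ValueError("no usable inner folds")
    truth = case_mask[usable]
    scores = []
    for g in grid:
        pred = predictions[g][usable].astype(bool)
        tp = int((pred & truth).sum())
        fn = int((~pred & truth).sum())
        tn = int((~pred & ~truth).sum())
        fp = int((pred & ~truth).sum())
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        scores.append((sens + spec) / 2.0)
    return select_smallest_best(grid, scores)


# ---------------------------------------------------------------------------
# Outer LOOCV

def _check_class_sizes(y: np.ndarray, case_label: str, control_label: str) -> None:
    n_case, n_ctrl = int(y.sum()), int((~y).sum())
    if n_case < 3 or n_ctrl < 3:
        raise ValueError(
            f"need >= 3 samples per class ({case_label}: {n_case}, "
            f"{control_label}: {n_ctrl})"
        )
    if n_case < 5 or n_ctrl < 5:
        logger.warning(
            "small class: %s=%d, %s=%d; estimates will be noisy",
            case_label, n_case, control_label, n_ctrl,
        )


def loocv_classify(
    expr: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    config: RunConfig | None = None,
    leaky: bool = False,
) -> ClassifierResult:
    """Nested leave-one-out classification of case vs control samples.

    ``labels`` holds exactly two label values; ``case_label`` marks the
    positive class.  With ``leaky=True`` gene ranking and gene-count
    selection are performed once on the full data (held-out sample
    included) — a deliberately information-leaking negative control.
    """
    config = config or RunConfig()
    labels = labels.loc[expr.columns]
    other = sorted(set(labels.unique()) - {case_label})
    if len(other) != 1:
        raise ValueError(f"expected exactly two label values, got {sorted(set(labels))}")
    control_label = other[0]
    y = (labels == case_label).to_numpy()
    _check_class_sizes(y, case_label, control_label)

    values = expr.to_numpy(dtype=float)
    tie_key = _lexical_ranks(expr.index.to_numpy(dtype=str))
    n = values.shape[1]

    if leaky:
        global_order, _ = _rank_order(values, y, tie_key)
        global_n = inner_select_n(values, y, tie_key, config)

    probs = np.empty(n)
    chosen: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if y_tr.sum() == 0 or (~y_tr).sum() == 0:
            raise ValueError(f"class absent from training fold {i}")
        if leaky:
            order, n_star = global_order, global_n
        else:
            order, _ = _rank_order(values[:, mask], y_tr, tie_key)
            n_star = inner_select_n(values[:, mask], y_tr, tie_key, config)
        top = order[:n_star]
        model = _FoldModel(
            config, seed=_fold_seed(config.seed, i), calibration_cv=config.calibration_cv
        )
        model.fit(values[np.ix_(top, mask)].T, y_tr)
        probs[i] = model.predict_proba(values[top, i])[0]
        chosen.append(int(n_star))

    pred = probs >= config.probability_threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    fisher_p = fisher_exact_two_sided(tp, fn, fp, tn)
    return ClassifierResult(
        sample_ids=[str(s) for s in expr.columns],
        true_labels=[case_label if v else control_label for v in y],
        probabilities=[float(p) for p in probs],
        predicted_labels=[case_label if v else control_label for v in pred],
        case_label=case_label,
        control_label=control_label,
        tp=tp, fn=fn, tn=tn, fp=fp,
        fisher_p=fisher_p,
        chosen_gene_counts=chosen,
    )


def loocv_fixed_genes(
    expr: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    genes: list[str],
    config: RunConfig | None = None,
) -> ClassifierResult:
    """LOOCV with a fixed gene set (no selection inside the folds).

    Used to evaluate a transferred signature in an external cohort: each
    fold standardizes the fixed genes with training statistics, trains the
    linear SVM, calibrates, predicts the held-out sample and adjusts for the
    training class imbalance.
    """
    config = config or RunConfig()
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:10]}")
    labels = labels.loc[expr.columns]
    other = sorted(set(labels.unique()) - {case_label})
    if len(other) != 1:
        raise ValueError(f"expected exactly two label values, got {sorted(set(labels))}")
    control_label = other[0]
    y = (labels == case_label).to_numpy()
    _check_class_sizes(y, case_label, control_label)

    values = expr.loc[genes].to_numpy(dtype=float)
    n = values.shape[1]
    probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = _FoldModel(
            config, seed=_fold_seed(config.seed, i), calibration_cv=config.calibration_cv
        )
        model.fit(values[:, mask].T, y[mask])
        probs[i] = model.predict_proba(values[:, i])[0]

    pred = probs >= config.probability_threshold
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    return ClassifierResult(
        sample_ids=[str(s) for s in expr.columns],
        true_labels=[case_label if v else control_label for v in y],
        probabilities=[float(p) for p in probs],
        predicted_labels=[case_label if v else control_label for v in pred],
        case_label=case_label,
        control_label=control_label,
        tp=tp, fn=fn, tn=tn, fp=fp,
        fisher_p=fisher_exact_two_sided(tp, fn, fp, tn),
    )


def stratified_classify(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    stratum_subtype: str,
    case_label: str,
    config: RunConfig | None = None,
    leaky: bool = False,
) -> ClassifierResult:
    """Restrict to one molecular subtype, then run the nested LOOCV.

    ``stratum_subtype="all"`` skips the restriction (the confound-prone
    general classification).  Controls are the sporadic samples.
    """
    if annotation["subtype"].isna().any() and stratum_subtype != "all":
        raise ValueError("all samples need a subtype before stratification")
    keep = annotation["group"].isin([case_label, "sporadic"])
    if stratum_subtype != "all":
        keep &= annotation["subtype"] == stratum_subtype
    samples = annotation.index[keep]
    samples = [s for s in expr.columns if s in set(samples)]
    if not samples:
        raise ValueError(f"no samples in stratum {stratum_subtype!r}")
    labels = annotation.loc[samples, "group"]
    if (labels == case_label).sum() == 0 or (labels == "sporadic").sum() == 0:
        raise ValueError(
            f"stratum {stratum_subtype!r} lacks one of the classes "
            f"({case_label} vs sporadic)"
        )
    return loocv_classify(expr[samples], labels, case_label, config, leaky=leaky)
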