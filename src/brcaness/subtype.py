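"""Intrinsic molecular subtype assignment and unsupervised clustering.

Subtypes are called by nearest centroid under Spearman rank correlation
(PAM50-style, generalized to any user-supplied centroid table); clustering
follows the classical recipe: top-variance gene selection, per-gene
standardization, Euclidean distance, complete linkage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.stats import rankdata

from .containers import SUBTYPES, validate_centroids, validate_expression_matrix
from .stats import fisher_exact_two_sided

logger = logging.getLogger("brcaness")

MIN_SHARED_GENES = 10


def classify_subtypes(
    expr: pd.DataFrame,
    centroids: pd.DataFrame,
    median_center: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample to the centroid with the highest Spearman correlation.

    Genes are intersected by symbol; expression rows are median-centered
    across samples first (cross-platform convention for centroid
    classifiers).  Ties are broken in the fixed order ``basal,
    her2_enriched, lumA, lumB, normal_like`` with a logged warning.

    Returns
    -------
    (subtype calls indexed by sample, samples x subtypes correlation table)
    """
    validate_expression_matrix(expr)
    validate_centroids(centroids)
    shared = expr.index.intersection(centroids.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids "
            f"(need >= {MIN_SHARED_GENES})"
        )
    x = expr.loc[shared].to_numpy(dtype=float)
    if median_center:
        x = x - np.median(x, axis=1, keepdims=True)
    c = centroids.loc[shared, list(SUBTYPES)].to_numpy(dtype=float)

    # Spearman = Pearson on mid-ranks; rank within each sample / centroid
    rx = rankdata(x, axis=0)
    rc = rankdata(c, axis=0)
    rx = rx - rx.mean(axis=0, keepdims=True)
    rc = rc - rc.mean(axis=0, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=0))[:, None] * np.sqrt((rc**2).sum(axis=0))[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (rx.T @ rc) / denom
    corr = np.where(np.isfinite(corr), corr, -np.inf)

    calls = []
    for i, sample in enumerate(expr.columns):
        best = corr[i].max()
        winners = [SUBTYPES[j] for j in range(len(SUBTYPES)) if corr[i, j] == best]
        if len(winners) > 1:
            logger.warning(
                "subtype tie for sample %s between %s; using %s",
                sample, winners, winners[0],
            )
        calls.append(winners[0])
    corr_df = pd.DataFrame(corr, index=expr.columns, columns=list(SUBTYPES))
    return pd.Series(calls, index=expr.columns, name="subtype"), corr_df


def subtype_enrichment(annotation: pd.DataFrame) -> pd.DataFrame:
    """Group-vs-rest x subtype-vs-rest Fisher tests over all pairs.

    Each (group, subtype) pair is collapsed to a 2x2 table; the two-sided
    exact p quantifies enrichment of that group in that subtype.
    """
    if annotation["subtype"].isna().any() or annotation["group"].isna().any():
        raise ValueError("subtype_enrichment requires group and subtype for all samples")
    total = len(annotation)
    rows = []
    for group in sorted(annotation["group"].unique()):
        in_group = annotation["group"] == group
        for st in SUBTYPES:
            in_st = annotation["subtype"] == st
            a = int((in_group & in_st).sum())
            b = int((in_group & ~in_st).sum())
            c = int((~in_group & in_st).sum())
            d = total - a - b - c
            if a + b == 0 or a + c == 0:
                continue
            rows.append(
                {
                    "group": group,
                    "subtype": st,
                    "n_group_subtype": a,
                    "n_group_other": b,
                    "n_rest_subtype": c,
                    "n_rest_other": d,
                    "fisher_p": fisher_exact_two_sided(a, b, c, d),
                }
            )
    if not rows:
        raise ValueError("empty margins: no testable (group, subtype) pairs")
    return pd.DataFrame(rows)


def top_variant_genes(expr: pd.DataFrame, n_top: int) -> pd.Index:
    """The ``n_top`` genes with the largest variance across samples.

    Ties in variance are broken by lexical gene-symbol order (determinism).
    """
    if n_top > len(expr):
        raise ValueError(f"n_top={n_top} exceeds gene count {len(expr)}")
    variances = expr.var(axis=1, ddof=1)
    order = (
        pd.DataFrame({"var": variances, "gene": variances.index.astype(str)})
        .sort_values(["var", "gene"], ascending=[False, True], kind="mergesort")
    )
    return pd.Index(order.index[:n_top])


def cluster_samples(
    expr: pd.DataFrame, n_top_variant: int = 500
) -> tuple[np.ndarray, list[str]]:
    """Hierarchical clustering of samples (Euclidean, complete linkage).

    The top-variance genes are standardized to zero mean / unit variance
    before distances are computed.  Returns the scipy linkage matrix and the
    dendrogram-ordered sample list.
    """
    validate_expression_matrix(expr)
    if expr.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    genes = top_variant_genes(expr, min(n_top_variant, len(expr)))
    x = expr.loc[genes].to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    z = (x - mean) / sd
    link = linkage(z.T, method="complete", metric="euclidean")
    order = [expr.columns[i] for i in leaves_list(link)]
    return link, order


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = to_tree(link)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
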