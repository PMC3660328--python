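"""Receptor-status derivation from marker-gene expression.

ER, PR and HER2 statuses are inferred from the expression of ESR1, PGR and
ERBB2 (configurable): the bimodal marker distribution is split at the valley
of its kernel density estimate, and samples at or above the cutoff are
called positive.  When immunohistochemistry (IHC) labels are available the
expression/IHC concordance is reported as a ROC AUC, and a unimodal marker
falls back to the Youden-J optimal ROC cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .config import RunConfig
from .stats import UnimodalError, density_valley_cutoff, roc_auc

logger = logging.getLogger("brcaness")

AUC_WARN_THRESHOLD = 0.8


@dataclass(frozen=True)
class MarkerDerivation:
    """Cutoff and (optional) IHC concordance for one marker gene."""

    cutoff: float
    auc: float | None
    method: str  # "density_valley" or "youden_j"


def derive_marker_status(
    expr_row,
    ihc_labels=None,
    bandwidth: str | float = "silverman",
) -> tuple[pd.Series, MarkerDerivation]:
    """Derive positive/negative status from one marker gene's expression.

    Samples exactly at the cutoff count as positive.  Raises
    :class:`brcaness.stats.UnimodalError` if the distribution is unimodal
    and no IHC labels are available for a supervised fallback.
    """
    values = pd.Series(expr_row).astype(float)
    labels = None
    if ihc_labels is not None:
        labels = np.asarray(ihc_labels).astype(float)
        if len(labels) != len(values):
            raise ValueError("ihc_labels must align with expression values")

    try:
        cutoff = density_valley_cutoff(values.to_numpy(), bandwidth=bandwidth)
        method = "density_valley"
    except UnimodalError:
        if labels is None:
            raise
        mask = np.isfinite(labels)
        fpr, tpr, thresholds = roc_curve(labels[mask], values.to_numpy()[mask])
        cutoff = float(thresholds[np.argmax(tpr - fpr)])
        method = "youden_j"
        logger.warning("marker unimodal; using Youden-J cutoff %.3f from IHC", cutoff)

    status = pd.Series(
        np.where(values >= cutoff, "positive", "negative"),
        index=values.index, dtype=object,
    )
    auc = None
    if labels is not None:
        mask = np.isfinite(labels)
        auc = roc_auc(values.to_numpy()[mask], labels[mask].astype(bool))
        if auc < AUC_WARN_THRESHOLD:
            logger.warning("marker/IHC AUC %.3f below %.2f", auc, AUC_WARN_THRESHOLD)
    return status, MarkerDerivation(float(cutoff), auc, method)


def derive_all_statuses(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, MarkerDerivation]]:
    """Attach derived er/pr/her2 statuses to a copy of the annotation table.

    IHC labels already present in the annotation (``positive``/``negative``)
    are used to report concordance; the derived (expression-based) statuses
    overwrite the status columns.
    """
    config = config or RunConfig()
    ann = annotation.copy()
    meta: dict[str, MarkerDerivation] = {}
    for receptor, gene in config.marker_genes.items():
        col = f"{receptor}_status"
        if gene not in expr.index:
            raise KeyError(f"marker gene {gene!r} absent from expression matrix")
        ihc = None
        if col in ann.columns and ann[col].isin(["positive", "negative"]).any():
            ihc = ann[col].map({"positive": 1.0, "negative": 0.0}).to_numpy()
        status, derivation = derive_marker_status(
            expr.loc[gene, ann.index], ihc, bandwidth=config.kde_bandwidth
        )
        ann[col] = status.values
        meta[receptor] = derivation
    return ann, meta


def triple_negative(annotation: pd.DataFrame) -> pd.Series:
    """ER-/PR-/HER2- phenotype per sample; pd.NA if any status is unknown."""
    cols = ["er_status", "pr_status", "her2_status"]
    missing = [c for c in cols if c not in annotation.columns]
    if missing:
        raise KeyError(f"annotation missing status columns: {missing}")
    sub = annotation[cols]
    known = sub.isin(["positive", "negative"]).all(axis=1)
    all_neg = (sub == "negative").all(axis=1)
    out = pd.Series(pd.NA, index=annotation.index, dtype="boolean")
    out[known] = all_neg[known]
    return out
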