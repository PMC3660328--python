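"""Derivation, transfer and external validation of fixed gene signatures.

A signature is derived on a full cohort: genes are ranked by Welch-t using
all samples, and the signature length is the smallest top-N gene count
maximizing LOOCV balanced accuracy over a candidate grid.  Because the
ranking sees every sample, the internal LOOCV estimate is optimistic; the
honest performance estimate comes from validating the fixed signature in an
independent cohort (gene-overlap transfer followed by LOOCV there).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import loocv_fixed_genes, rank_genes, select_smallest_best
from .config import RunConfig
from .containers import ClassifierResult, GeneSignature, SignatureEntry

logger = logging.getLogger("brcaness")

MIN_OVERLAP = 10


def derive_signature(
    expr: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    config: RunConfig | None = None,
    name: str = "signature",
    stratum: str = "all",
) -> tuple[GeneSignature, pd.DataFrame]:
    """Derive a fixed signature from a full cohort.

    Returns the signature plus the accuracy-vs-length profile (one row per
    candidate gene count with its LOOCV balanced accuracy).  The signature
    is "training-derived": its internal accuracy is an optimistic estimate.
    """
    config = config or RunConfig()
    labels = labels.loc[expr.columns]
    y = labels == case_label
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present to derive a signature")
    grid = [g for g in config.gene_count_grid if g <= len(expr)]
    if not grid:
        raise ValueError("gene_count_grid has no entry <= gene count")

    ranking = rank_genes(expr, y.to_numpy())
    profile = []
    for n in grid:
        genes = list(ranking.index[:n])
        result = loocv_fixed_genes(expr, labels, case_label, genes, config)
        profile.append({"n_genes": n, "balanced_accuracy": result.balanced_accuracy})
    profile_df = pd.DataFrame(profile)
    length = select_smallest_best(
        profile_df["n_genes"], profile_df["balanced_accuracy"]
    )
    best = profile_df.loc[profile_df["n_genes"] == length, "balanced_accuracy"].iloc[0]

    entries = tuple(
        SignatureEntry(str(g), float(t))
        for g, t in ranking["t_statistic"].iloc[:length].items()
    )
    sig = GeneSignature(name=name, entries=entries, case_label=case_label, stratum=stratum)
    logger.info(
        "derived signature %s: length=%d internal_ba=%.3f (training-derived, optimistic)",
        name, length, best,
    )
    return sig, profile_df


def transfer_signature(
    signature: GeneSignature, external_expr: pd.DataFrame
) -> tuple[list[str], float]:
    """Intersect a signature with an external matrix's gene vocabulary.

    Order is preserved and genes are never renamed; returns the overlap list
    and the coverage fraction ``|overlap| / length``.
    """
    present = set(external_expr.index)
    overlap = [g for g in signature.genes if g in present]
    coverage = len(overlap) / signature.length
    if len(overlap) < MIN_OVERLAP:
        raise ValueError(
            f"signature {signature.name!r}: only {len(overlap)} of "
            f"{signature.length} genes present in external matrix "
            f"(need >= {MIN_OVERLAP})"
        )
    logger.info(
        "transfer %s: %d/%d genes present (coverage %.2f)",
        signature.name, len(overlap), signature.length, coverage,
    )
    return overlap, coverage


def validate_signature(
    signature: GeneSignature,
    external_expr: pd.DataFrame,
    external_labels: pd.Series,
    config: RunConfig | None = None,
) -> tuple[ClassifierResult, list[str], float]:
    """Evaluate a fixed signature in an independent cohort by LOOCV.

    The overlapping genes are used as-is (no re-selection); per-fold
    standardization makes the classifier scale-free within the external
    dataset, so cross-platform scale differences do not matter.
    """
    config = config or RunConfig()
    overlap, coverage = transfer_signature(signature, external_expr)
    result = loocv_fixed_genes(
        external_expr, external_labels, signature.case_label, overlap, config
    )
    return result, overlap, coverage
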