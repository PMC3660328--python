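"""In-memory data containers and their invariants.

Expression matrices, sample annotations and subtype centroids are plain
:class:`pandas.DataFrame` objects (genes as rows / samples as columns for
matrices; samples as rows for annotations); the ``validate_*`` functions
enforce the structural invariants every pipeline stage relies on.  Gene
signatures and classifier results are small dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical intrinsic-subtype order; also the deterministic tie-break order
#: for nearest-centroid calls.
SUBTYPES = ("basal", "her2_enriched", "lumA", "lumB", "normal_like")

GROUPS = ("BRCA1", "BRCA2", "sporadic")

STATUSES = ("positive", "negative", "unknown")

ANNOTATION_COLUMNS = (
    "group",
    "er_status",
    "pr_status",
    "her2_status",
    "age_years",
    "subtype",
)


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes[:10]}")


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples log2-ratio matrix.

    Gene symbols (row index) and sample IDs (columns) must be unique and all
    values numeric; NaN encodes explicitly missing values.
    """
    _check_unique(expr.index, "gene symbols")
    _check_unique(expr.columns, "sample IDs")
    values = expr.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValidationError("expression matrix contains non-numeric values")
    if values.size and np.isinf(values).any():
        bad = np.argwhere(np.isinf(values))[0]
        raise ValidationError(
            f"non-finite value at gene {expr.index[bad[0]]!r}, "
            f"sample {expr.columns[bad[1]]!r}"
        )
    return expr


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample annotation table (index = sample_id)."""
    _check_unique(ann.index, "sample IDs")
    if "group" not in ann.columns:
        raise ValidationError("annotation must have a 'group' column")
    bad_groups = set(ann["group"].dropna()) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
    for col in ("er_status", "pr_status", "her2_status"):
        if col in ann.columns:
            bad = set(ann[col].dropna()) - set(STATUSES)
            if bad:
                raise ValidationError(f"unknown {col} values: {sorted(bad)}")
    if "subtype" in ann.columns:
        bad = set(ann["subtype"].dropna()) - set(SUBTYPES) - {"unassigned"}
        if bad:
            raise ValidationError(f"unknown subtype labels: {sorted(bad)}")
    if "age_years" in ann.columns:
        ages = pd.to_numeric(ann["age_years"], errors="coerce")
        if (ages.dropna() < 0).any():
            raise ValidationError("negative age_years")
    return ann


def validate_centroids(centroids: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x 5 subtype-centroid table."""
    _check_unique(centroids.index, "centroid gene symbols")
    _check_unique(centroids.columns, "subtype names")
    missing = set(SUBTYPES) - set(centroids.columns)
    if missing:
        raise ValidationError(f"centroid table missing subtypes: {sorted(missing)}")
    if len(centroids.index) < 2:
        raise ValidationError("centroid table needs at least 2 genes")
    return centroids


@dataclass(frozen=True)
class SignatureEntry:
    """One signature gene with its ranking statistic."""

    gene_symbol: str
    t_statistic: float

    @property
    def direction(self) -> str:
        """``up_in_case`` if the gene is higher in carriers, else ``down_in_case``."""
        return "up_in_case" if self.t_statistic >= 0 else "down_in_case"


@dataclass(frozen=True)
class GeneSignature:
    """An ordered, fixed gene list for classifying new samples.

    Entries are sorted by decreasing ``|t|``; ``case_label`` names the carrier
    class the signature separates from sporadic tumors and ``stratum`` the
    molecular subtype it was derived within (or ``"all"``).
    """

    name: str
    entries: tuple[SignatureEntry, ...]
    case_label: str
    stratum: str = "all"

    def __post_init__(self) -> None:
        symbols = [e.gene_symbol for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        abs_t = [abs(e.t_statistic) for e in self.entries]
        if any(a < b - 1e-12 for a, b in zip(abs_t, abs_t[1:])):
            raise ValidationError(
                f"signature {self.name!r} entries not sorted by decreasing |t|"
            )

    @property
    def length(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]


@dataclass
class ClassifierResult:
    """Per-sample LOOCV probabilities plus aggregate performance."""

    sample_ids: list[str]
    true_labels: list[str]
    probabilities: list[float]
    predicted_labels: list[str]
    case_label: str
    control_label: str
    tp: int
    fn: int
    tn: int
    fp: int
    fisher_p: float
    chosen_gene_counts: list[int] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.true_labels) == len(self.probabilities) == len(self.predicted_labels) == n):
            raise ValidationError("per-sample fields have inconsistent lengths")
        n_cases = sum(1 for t in self.true_labels if t == self.case_label)
        n_controls = n - n_cases
        if self.tp + self.fn != n_cases or self.tn + self.fp != n_controls:
            raise ValidationError("confusion counts inconsistent with true labels")
        if not all(0.0 <= p <= 1.0 or math.isnan(p) for p in self.probabilities):
            raise ValidationError("probabilities outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "case_label": self.case_label,
            "control_label": self.control_label,
            "n_cases": self.tp + self.fn,
            "n_controls": self.tn + self.fp,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "fisher_p": self.fisher_p,
            "chosen_gene_counts": list(self.chosen_gene_counts),
            "samples": [
                {
                    "sample_id": s,
                    "true_label": t,
                    "probability": p,
                    "predicted_label": y,
                }
                for s, t, p, y in zip(
                    self.sample_ids,
                    self.true_labels,
                    self.probabilities,
                    self.predicted_labels,
                )
            ],
        }
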