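"""Reading and writing of on-disk artifacts.

All tabular artifacts are tab-separated text with a mandatory header row;
missing values are encoded as ``NA``.  Floats are written at full (repr)
precision so that write -> read round-trips are lossless to 1e-12.
Classifier results and run reports are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .containers import (
    ClassifierResult,
    GeneSignature,
    SignatureEntry,
    ValidationError,
    validate_annotation,
    validate_centroids,
    validate_expression_matrix,
)

logger = logging.getLogger("brcaness")

_NA = "NA"


def log_stage(stage: str, **fields) -> None:
    """One structured log line per pipeline stage (auditability of filtering)."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, payload)


# ---------------------------------------------------------------------------
# Expression matrices

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample TSV matrix (first column = gene symbol).

    Duplicate gene symbols are rejected: probe-level data must be collapsed
    (see :func:`brcaness.preprocess.collapse_probes`) before it becomes an
    expression matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbols in {path.name}: {dupes[:10]}")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric cell in {path.name} at gene {row!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.index.name = "gene_symbol"
    log_stage("read_expression_matrix", path=path.name, shape=df.shape)
    return validate_expression_matrix(df)


def write_expression_matrix(expr: pd.DataFrame, path: str | Path) -> None:
    validate_expression_matrix(expr)
    expr = expr.copy()
    expr.index.name = "gene_symbol"
    expr.to_csv(path, sep="\t", na_rep=_NA)


# ---------------------------------------------------------------------------
# Sample annotations

def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if "age_years" in df.columns:
        df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    log_stage("read_annotation", path=path.name, n_samples=len(df))
    return validate_annotation(df)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(ann)
    ann = ann.copy()
    ann.index.name = "sample_id"
    ann.to_csv(path, sep="\t", na_rep=_NA)


# ---------------------------------------------------------------------------
# Subtype centroids

def read_centroids(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    df.index = df.index.astype(str)
    df.index.name = "gene_symbol"
    log_stage("read_centroids", path=path.name, n_genes=len(df))
    return validate_centroids(df)


def write_centroids(centroids: pd.DataFrame, path: str | Path) -> None:
    validate_centroids(centroids)
    centroids = centroids.copy()
    centroids.index.name = "gene_symbol"
    centroids.to_csv(path, sep="\t", na_rep=_NA)


# ---------------------------------------------------------------------------
# Gene signatures

_SIG_COLUMNS = ["rank", "gene_symbol", "t_statistic", "direction"]


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    """Persist a signature as TSV with a ``#`` metadata header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# name={sig.name}\tcase_label={sig.case_label}\t"
            f"stratum={sig.stratum}\tlength={sig.length}\n"
        )
        fh.write("\t".join(_SIG_COLUMNS) + "\n")
        for rank, entry in enumerate(sig.entries, start=1):
            fh.write(
                f"{rank}\t{entry.gene_symbol}\t{entry.t_statistic!r}\t{entry.direction}\n"
            )


def read_signature(path: str | Path) -> GeneSignature:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValidationError(f"{path.name}: missing metadata header line")
        meta = dict(
            field.split("=", 1) for field in header.lstrip("#").strip().split("\t")
        )
        body = pd.read_csv(fh, sep="\t")
    if body.empty:
        raise ValidationError(f"{path.name}: signature file has no entries")
    if list(body.columns) != _SIG_COLUMNS:
        raise ValidationError(f"{path.name}: expected columns {_SIG_COLUMNS}")
    declared = int(meta.get("length", -1))
    if declared != len(body):
        raise ValidationError(
            f"{path.name}: declared length {declared} != {len(body)} entries"
        )
    entries = tuple(
        SignatureEntry(str(row.gene_symbol), float(row.t_statistic))
        for row in body.itertuples()
    )
    return GeneSignature(
        name=meta.get("name", path.stem),
        entries=entries,
        case_label=meta.get("case_label", "BRCA1"),
        stratum=meta.get("stratum", "all"),
    )


# ---------------------------------------------------------------------------
# Classifier results / reports

def write_classifier_result(result: ClassifierResult, path: str | Path, **extra) -> None:
    payload = result.to_dict()
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_two_color_batch(path: str | Path) -> pd.DataFrame:
    """Read a long-format raw two-color intensity table.

    Columns: probe_id, gene_symbol, array_id, fg_cy5, bg_cy5, fg_cy3, bg_cy3.
    An empty gene_symbol marks an unannotated probe.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", na_values=[_NA], keep_default_na=False,
        dtype={"probe_id": str, "gene_symbol": str, "array_id": str},
    )
    required = {"probe_id", "gene_symbol", "array_id", "fg_cy5", "bg_cy5", "fg_cy3", "bg_cy3"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path.name}: missing columns {sorted(missing)}")
    log_stage("read_two_color_batch", path=path.name, n_rows=len(df))
    return df


def write_two_color_batch(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
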