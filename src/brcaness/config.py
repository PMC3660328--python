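"""Run configuration: defaults, YAML loading and validation."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("brcaness")

#: Default seed used when a config omits one; documented so runs without an
#: explicit seed are still reproducible.
DEFAULT_SEED = 0


def default_gene_grid() -> list[int]:
    """Gene-count grid for nested selection: 5, 10, ..., 200."""
    return list(range(5, 205, 5))


@dataclass
class RunConfig:
    """Validated configuration shared by the pipeline stages.

    Parameters
    ----------
    probability_threshold:
        Samples with an adjusted carrier probability at or above this value
        are called carriers; 0.5 is prior-free after imbalance adjustment.
    gene_count_grid:
        Strictly increasing candidate signature sizes for the nested
        selection loop.
    svm_cost:
        Soft-margin cost C of the linear-kernel SVM (not tuned).
    normexp_offset:
        Constant added to background-corrected intensities before log2.
    loess_span, loess_iterations:
        MA-loess smoother span and number of robustness iterations.
    standardize_genes:
        Standardize each selected gene with training-fold statistics before
        the margin classifier.
    calibration_cv:
        Folds of seeded cross-validated decision values used to fit the
        Platt sigmoid (0 = fit on training decision values directly).
    marker_genes:
        Mapping receptor -> marker gene symbol used for status derivation.
    """

    seed: int = DEFAULT_SEED
    probability_threshold: float = 0.5
    gene_count_grid: list[int] = field(default_factory=default_gene_grid)
    svm_cost: float = 1.0
    standardize_genes: bool = True
    calibration_cv: int = 3
    normexp_offset: float = 50.0
    loess_span: float = 0.3
    loess_iterations: int = 4
    quantile_target: str = "channels"
    n_top_variant: int = 500
    kde_bandwidth: str | float = "silverman"
    marker_genes: dict = field(
        default_factory=lambda: {"er": "ESR1", "pr": "PGR", "her2": "ERBB2"}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.probability_threshold < 1.0:
            raise ValueError("probability_threshold: must be in (0, 1)")
        grid = list(self.gene_count_grid)
        if not grid:
            raise ValueError("gene_count_grid: must not be empty")
        if any(int(n) <= 0 for n in grid):
            raise ValueError("gene_count_grid: values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("gene_count_grid: must be strictly increasing")
        self.gene_count_grid = [int(n) for n in grid]
        if self.svm_cost <= 0:
            raise ValueError("svm_cost: must be positive")
        if self.normexp_offset < 0:
            raise ValueError("normexp_offset: must be >= 0")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span: must be in (0, 1]")
        if self.quantile_target not in ("channels", "m"):
            raise ValueError("quantile_target: must be 'channels' or 'm'")
        self.seed = int(self.seed)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config, apply defaults, warn about unknown keys.

    ``overrides`` take precedence over file values.  Type or range problems
    raise :class:`ValueError` naming the offending key.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        raw.update(loaded)
    raw.update(overrides)

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    for key in sorted(unknown):
        logger.warning("config: ignoring unknown key %r", key)
    kwargs = {k: v for k, v in raw.items() if k in known}
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
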