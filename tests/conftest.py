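import numpy as np
import pandas as pd
import pytest

from brcaness.config import RunConfig


def make_expr(n_genes: int, n_samples: int, seed: int = 0, prefix: str = "G") -> pd.DataFrame:
    """Pure-noise expression matrix with deterministic gene/sample names."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=pd.Index([f"{prefix}{i:05d}" for i in range(n_genes)], name="gene_symbol"),
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )


def planted_cohort(
    n_genes: int = 500,
    n_cases: int = 15,
    n_controls: int = 25,
    n_effect: int = 30,
    delta: float = 1.5,
    seed: int = 0,
):
    """Noise matrix with a planted case-vs-control shift on the first genes."""
    expr = make_expr(n_genes, n_cases + n_controls, seed=seed)
    rng = np.random.default_rng(seed + 1)
    signs = rng.choice([-1.0, 1.0], size=n_effect)
    expr.iloc[:n_effect, :n_cases] = (
        expr.iloc[:n_effect, :n_cases].to_numpy() + delta * signs[:, None]
    )
    labels = pd.Series(
        ["case"] * n_cases + ["control"] * n_controls, index=expr.columns
    )
    effect_genes = list(expr.index[:n_effect])
    return expr, labels, effect_genes


@pytest.fixture
def small_config():
    """A fast configuration for nested-LOOCV tests."""
    return RunConfig(seed=0, gene_count_grid=[5, 15, 30])
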