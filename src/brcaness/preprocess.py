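"""Two-color microarray preprocessing.

Raw probe intensities are converted to a gene-level log2 Cy5/Cy3 ratio
matrix in the order: normexp background correction per channel -> log2 ->
within-array MA-loess normalization -> between-array quantile normalization
of the M values -> collapsing of probes to unique gene symbols.

The normexp model treats the net intensity of each spot as
``X = S + B`` with signal ``S ~ Exponential(mean alpha)`` and background
``B ~ Normal(mu, sigma^2)``.  Parameters are fitted by direct numerical
maximum likelihood; the correction replaces ``x`` by the posterior mean
``E[S | X = x]``, which is strictly positive and monotone in ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ValidationError, validate_expression_matrix
from .config import RunConfig
from .io import log_stage

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class NormexpParams:
    """Background mean/sd and exponential signal mean of the normexp model."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.alpha <= 0:
            raise ValueError("normexp requires sigma > 0 and alpha > 0")


def _normexp_loglik(x: np.ndarray, mu: float, sigma: float, alpha: float) -> float:
    # log f(x) = -log(alpha) + (mu - x)/alpha + sigma^2/(2 alpha^2)
    #            + log Phi((x - mu)/sigma - sigma/alpha)
    z = (x - mu) / sigma - sigma / alpha
    ll = -np.log(alpha) + (mu - x) / alpha + sigma**2 / (2.0 * alpha**2) + log_ndtr(z)
    return float(np.sum(ll))


def normexp_fit(fg, bg=None) -> NormexpParams:
    """Maximum-likelihood normexp fit on net intensities ``x = fg - bg``.

    Initialized from the first three moments (the exponential component
    carries all the skewness: ``E[(X - EX)^3] = 2 alpha^3``), then refined by
    Nelder-Mead on ``(mu, log sigma, log alpha)``.
    """
    x = np.asarray(fg, dtype=float)
    if bg is not None:
        x = x - np.asarray(bg, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 100:
        raise ValueError("normexp_fit requires at least 100 probes")
    if np.ptp(x) == 0.0:
        raise ValueError("normexp_fit: degenerate input (all net intensities equal)")

    m1 = x.mean()
    m2 = x.var()
    m3 = np.mean((x - m1) ** 3)
    alpha0 = max((m3 / 2.0) ** (1.0 / 3.0), 1e-2 * np.sqrt(m2)) if m3 > 0 else 0.1 * np.sqrt(m2)
    sigma0 = np.sqrt(max(m2 - alpha0**2, 1e-4 * m2))
    mu0 = m1 - alpha0

    def nll(theta):
        mu, log_sigma, log_alpha = theta
        return -_normexp_loglik(x, mu, np.exp(log_sigma), np.exp(log_alpha))

    res = optimize.minimize(
        nll,
        x0=np.array([mu0, np.log(sigma0), np.log(alpha0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
    )
    mu, sigma, alpha = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    return NormexpParams(float(mu), sigma, alpha)


def normexp_correct(x, params: NormexpParams, offset: float = 0.0) -> np.ndarray:
    """Posterior-mean signal ``E[S | X = x] + offset``; strictly positive.

    With ``mu_s = x - mu - sigma^2/alpha`` the conditional mean is
    ``mu_s + sigma * phi(mu_s/sigma) / Phi(mu_s/sigma)`` (a truncated-normal
    mean), evaluated in log space for numerical stability far in the tails.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    x = np.asarray(x, dtype=float)
    mu_s = x - params.mu - params.sigma**2 / params.alpha
    z = mu_s / params.sigma
    log_phi = -0.5 * z**2 - _LOG_SQRT_2PI
    mills = np.exp(log_phi - log_ndtr(z))  # phi(z)/Phi(z), -> -z as z -> -inf
    signal = mu_s + params.sigma * mills
    return np.maximum(signal, np.finfo(float).tiny) + offset


def ma_loess_normalize(
    log_r, log_g, span: float = 0.3, iterations: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Within-array loess normalization on the MA plane.

    ``M = log_r - log_g`` is regressed on ``A = (log_r + log_g)/2`` with a
    robust local linear smoother; the fitted intensity-dependent dye bias is
    subtracted.  Returns ``(M_normalized, A)``.
    """
    log_r = np.asarray(log_r, dtype=float)
    log_g = np.asarray(log_g, dtype=float)
    m = log_r - log_g
    a = (log_r + log_g) / 2.0
    if len(m) < 10:
        raise ValueError("ma_loess_normalize requires at least 10 probes")
    fit = lowess(m, a, frac=span, it=iterations, return_sorted=False)
    return m - fit, a


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all columns (arrays) to share the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; tied entries receive the mean of the reference
    quantiles their positions span (deterministic and permutation-invariant).
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile_normalize requires a complete matrix")
    n, k = values.shape
    if k == 1:
        return df.copy()
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        uniq, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        counts = np.bincount(inverse)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_ids,
    probe_symbols,
    mean_cy5,
) -> pd.DataFrame:
    """Collapse a probe-level log2-ratio matrix to unique gene symbols.

    Step 1: replicate spots sharing a ``probe_id`` are collapsed to their
    per-array median.  Step 2: probes without a gene-symbol annotation are
    removed.  Step 3: when several probes map to one symbol, only the probe
    with the highest mean Cy5 foreground intensity is kept.
    """
    probe_ids = pd.Series(np.asarray(probe_ids, dtype=object), name="probe_id")
    symbols = pd.Series(np.asarray(probe_symbols, dtype=object), name="gene_symbol")
    cy5 = pd.Series(np.asarray(mean_cy5, dtype=float), name="mean_cy5")
    if not (len(probe_ids) == len(symbols) == len(cy5) == len(probe_matrix)):
        raise ValueError("probe metadata must align with the probe matrix rows")

    mat = probe_matrix.reset_index(drop=True)
    # step 1: median over replicate spots
    collapsed = mat.groupby(probe_ids.values, sort=True).median()
    meta = pd.DataFrame({"gene_symbol": symbols.values, "mean_cy5": cy5.values},
                        index=probe_ids.values)
    meta = meta.groupby(level=0, sort=True).agg({"gene_symbol": "first", "mean_cy5": "mean"})

    # step 2: drop unannotated probes
    sym = meta["gene_symbol"].astype(object)
    annotated = sym.notna() & (sym.astype(str).str.strip() != "")
    n_dropped = int((~annotated).sum())
    if n_dropped:
        log_stage("collapse_probes", dropped_unannotated=n_dropped)
    collapsed = collapsed.loc[annotated.values]
    meta = meta.loc[annotated.values]
    if collapsed.empty:
        raise ValidationError("no annotated probes left after filtering")

    # step 3: one probe per symbol, highest mean Cy5 (ties: lexically first probe_id)
    meta = meta.assign(probe_id=meta.index)
    meta_sorted = meta.sort_values(
        ["gene_symbol", "mean_cy5", "probe_id"], ascending=[True, False, True],
        kind="mergesort",
    )
    keep = meta_sorted.drop_duplicates("gene_symbol", keep="first")
    out = collapsed.loc[keep["probe_id"].values]
    out.index = pd.Index(keep["gene_symbol"].astype(str).values, name="gene_symbol")
    out = out.sort_index()
    log_stage("collapse_probes", n_probes_in=len(probe_matrix), n_genes_out=len(out))
    return validate_expression_matrix(out)


def preprocess_pipeline(batch: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Full preprocessing of a long-format two-color batch.

    ``batch`` columns: probe_id, gene_symbol, array_id, fg_cy5, bg_cy5,
    fg_cy3, bg_cy3 (one row per spot per array).  Spots with any missing
    intensity are dropped (logged).  Returns the collapsed gene x sample
    log2-ratio matrix.

    By default the between-array quantile step acts on the individual
    channel log-intensities (reconstituted from the loess-normalized M and
    A), which leaves genuine differential log-ratios intact; set
    ``config.quantile_target = "m"`` to quantile-normalize the M values
    directly (this visibly compresses effects present in only a subset of
    arrays).
    """
    config = config or RunConfig()
    required = ["probe_id", "gene_symbol", "array_id", "fg_cy5", "bg_cy5", "fg_cy3", "bg_cy3"]
    missing_cols = set(required) - set(batch.columns)
    if missing_cols:
        raise ValueError(f"batch missing columns: {sorted(missing_cols)}")

    batch = batch.copy()
    intensity_cols = ["fg_cy5", "bg_cy5", "fg_cy3", "bg_cy3"]
    complete = batch[intensity_cols].notna().all(axis=1)
    if (~complete).any():
        log_stage("preprocess_pipeline", dropped_incomplete_spots=int((~complete).sum()))
        batch = batch.loc[complete]

    # spot key: replicate spots of one probe on one array get occurrence numbers
    batch["_occ"] = batch.groupby(["array_id", "probe_id"]).cumcount()
    arrays = sorted(batch["array_id"].unique())

    m_cols: dict[str, pd.Series] = {}
    a_cols: dict[str, pd.Series] = {}
    for array_id in arrays:
        sub = batch.loc[batch["array_id"] == array_id].set_index(["probe_id", "_occ"])
        params_r = normexp_fit(sub["fg_cy5"].to_numpy(), sub["bg_cy5"].to_numpy())
        params_g = normexp_fit(sub["fg_cy3"].to_numpy(), sub["bg_cy3"].to_numpy())
        r = normexp_correct(sub["fg_cy5"] - sub["bg_cy5"], params_r, config.normexp_offset)
        g = normexp_correct(sub["fg_cy3"] - sub["bg_cy3"], params_g, config.normexp_offset)
        m_norm, a_vals = ma_loess_normalize(
            np.log2(r), np.log2(g),
            span=config.loess_span, iterations=config.loess_iterations,
        )
        m_cols[array_id] = pd.Series(m_norm, index=sub.index)
        a_cols[array_id] = pd.Series(a_vals, index=sub.index)
        log_stage(
            "normexp", array=array_id,
            mu=round(params_r.mu, 3), sigma=round(params_r.sigma, 3),
            alpha=round(params_r.alpha, 3),
        )

    m_matrix = pd.DataFrame(m_cols)
    a_matrix = pd.DataFrame(a_cols)
    spots_complete = m_matrix.notna().all(axis=1) & a_matrix.notna().all(axis=1)
    if (~spots_complete).any():
        log_stage("preprocess_pipeline", dropped_unbalanced_spots=int((~spots_complete).sum()))
        m_matrix = m_matrix.loc[spots_complete]
        a_matrix = a_matrix.loc[spots_complete]

    if config.quantile_target == "channels":
        # reconstitute channel log-intensities, quantile-normalize all 2k
        # channel columns to one target distribution, recompute M
        log_r = a_matrix + m_matrix / 2.0
        log_g = a_matrix - m_matrix / 2.0
        channels = pd.concat(
            {"R": log_r, "G": log_g}, axis=1
        )
        channels = quantile_normalize(channels)
        _assert_quantile_identity(channels)
        m_matrix = channels["R"] - channels["G"]
    else:
        m_matrix = quantile_normalize(m_matrix)
        _assert_quantile_identity(m_matrix)

    spot_meta = (
        batch.set_index(["probe_id", "_occ"])
        .loc[m_matrix.index, ["gene_symbol"]]
        .groupby(level=[0, 1])
        .first()
    )
    mean_cy5 = (
        batch.groupby(["probe_id", "_occ"])["fg_cy5"].mean().loc[m_matrix.index]
    )
    probe_ids = [pid for pid, _ in m_matrix.index]
    return collapse_probes(
        m_matrix.reset_index(drop=True),
        probe_ids,
        spot_meta["gene_symbol"].values,
        mean_cy5.values,
    )


def _assert_quantile_identity(matrix: pd.DataFrame, tol: float = 1e-12) -> None:
    """Post-condition of quantile normalization: identical sorted columns."""
    values = np.sort(matrix.to_numpy(dtype=float), axis=0)
    spread = np.abs(values - values[:, [0]]).max() if values.shape[1] > 1 else 0.0
    if spread > tol:
        raise AssertionError(f"quantile normalization violated: column spread {spread}")
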