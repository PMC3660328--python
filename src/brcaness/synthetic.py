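"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-color breast
cancer cohort: five intrinsic-subtype clusters, unequal carrier/sporadic
group sizes with the characteristic subtype skews (BRCA1 mostly basal-like,
BRCA2 mostly luminal B), bimodal receptor marker genes tied to subtype
identity, carrier-specific planted differential genes, and raw two-color
probe intensities following the exponential-signal-plus-Gaussian-background
convolution with a smooth intensity-dependent dye bias.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    SUBTYPES,
    validate_annotation,
    validate_centroids,
    validate_expression_matrix,
)
from .preprocess import NormexpParams

#: Group x subtype cell counts mirroring the study design: 33 BRCA1
#: (mostly basal-like), 22 BRCA2 (mostly lumB), 128 sporadic (lumA/lumB
#: majority).
DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("BRCA1", "basal"): 20,
    ("BRCA1", "lumB"): 9,
    ("BRCA1", "lumA"): 2,
    ("BRCA1", "her2_enriched"): 2,
    ("BRCA2", "lumB"): 16,
    ("BRCA2", "lumA"): 4,
    ("BRCA2", "normal_like"): 2,
    ("sporadic", "basal"): 10,
    ("sporadic", "lumA"): 55,
    ("sporadic", "lumB"): 48,
    ("sporadic", "her2_enriched"): 8,
    ("sporadic", "normal_like"): 7,
}

#: Subtypes in which each marker gene sits in its high mode.
_MARKER_HIGH = {
    "er": ("lumA", "lumB", "normal_like"),
    "pr": ("lumA", "lumB", "normal_like"),
    "her2": ("her2_enriched",),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic expression cohort.

    ``centroid_spread`` is the per-gene between-subtype standard deviation
    on the log2 scale; ``within_sd`` the within-subtype noise;
    ``effect_size`` (delta, log2 units) and ``effect_genes`` (D) define the
    planted carrier-vs-sporadic differential gene sets (disjoint between
    BRCA1 and BRCA2 and from the marker genes); ``marker_contrast`` is the
    half-distance between the two marker modes.
    """

    n_genes: int = 5000
    centroid_spread: float = 0.5
    within_sd: float = 0.5
    effect_size: float = 1.0
    effect_genes: int = 100
    marker_contrast: float = 2.0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    marker_genes: dict = field(
        default_factory=lambda: {"er": "ESR1", "pr": "PGR", "her2": "ERBB2"}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3 + 2 * self.effect_genes:
            raise ValueError("n_genes too small for markers plus two effect sets")
        if self.effect_size < 0 or any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("sizes and effect_size must be nonnegative")

    @property
    def gene_symbols(self) -> list[str]:
        markers = list(self.marker_genes.values())
        n_other = self.n_genes - len(markers)
        width = len(str(self.n_genes))
        return markers + [f"G{i:0{width}d}" for i in range(1, n_other + 1)]


def _streams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def make_centroids(spec: CohortSpec) -> pd.DataFrame:
    """Five subtype centroids with controlled between-subtype spread.

    Marker genes get subtype-consistent modes: the ER/PR markers are high in
    the luminal and normal-like centroids and low in basal/HER2-enriched;
    the HER2 marker is high only in the HER2-enriched centroid.
    """
    rng = np.random.default_rng(_streams(spec.seed, 4)[0])
    genes = spec.gene_symbols
    values = rng.normal(0.0, spec.centroid_spread, size=(spec.n_genes, len(SUBTYPES)))
    centroids = pd.DataFrame(values, index=pd.Index(genes, name="gene_symbol"),
                             columns=list(SUBTYPES))
    for receptor, symbol in spec.marker_genes.items():
        high = _MARKER_HIGH[receptor]
        centroids.loc[symbol] = [
            spec.marker_contrast if st in high else -spec.marker_contrast
            for st in SUBTYPES
        ]
    return validate_centroids(centroids)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw a full cohort: expression matrix, annotation and ground truth.

    Each sample is its subtype centroid plus iid Gaussian noise; carriers
    are additionally shifted by ``+/- effect_size`` on their group's planted
    gene set (sign fixed per gene).  Ground truth (planted gene lists, true
    receptor statuses) is returned for recovery tests.
    """
    if sum(spec.group_sizes.values()) == 0:
        raise ValueError("empty cohort")
    _, s_noise, s_signs, s_age = _streams(spec.seed, 4)
    rng = np.random.default_rng(s_noise)
    sign_rng = np.random.default_rng(s_signs)
    age_rng = np.random.default_rng(s_age)

    centroids = make_centroids(spec)
    genes = centroids.index
    n_markers = len(spec.marker_genes)
    d = spec.effect_genes
    effect1 = list(genes[n_markers : n_markers + d])
    effect2 = list(genes[n_markers + d : n_markers + 2 * d])
    signs1 = sign_rng.choice([-1.0, 1.0], size=d)
    signs2 = sign_rng.choice([-1.0, 1.0], size=d)

    columns: dict[str, np.ndarray] = {}
    rows = []
    counter = 0
    for group in ("BRCA1", "BRCA2", "sporadic"):
        for st in SUBTYPES:
            for _ in range(spec.group_sizes.get((group, st), 0)):
                counter += 1
                sample_id = f"S{counter:04d}"
                profile = centroids[st].to_numpy() + rng.normal(
                    0.0, spec.within_sd, size=spec.n_genes
                )
                if group == "BRCA1":
                    profile[n_markers : n_markers + d] += spec.effect_size * signs1
                elif group == "BRCA2":
                    profile[n_markers + d : n_markers + 2 * d] += spec.effect_size * signs2
                columns[sample_id] = profile
                if group == "sporadic":
                    age = age_rng.normal(61.0, 12.0)
                else:
                    age = age_rng.normal(43.0, 8.0)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "er_status": "positive" if st in _MARKER_HIGH["er"] else "negative",
                        "pr_status": "positive" if st in _MARKER_HIGH["pr"] else "negative",
                        "her2_status": "positive" if st in _MARKER_HIGH["her2"] else "negative",
                        "age_years": float(np.clip(round(age, 1), 25.0, 95.0)),
                        "subtype": st,
                    }
                )

    expr = pd.DataFrame(columns, index=genes)
    ann = pd.DataFrame(rows).set_index("sample_id")
    validate_expression_matrix(expr)
    validate_annotation(ann)
    truth = {
        "brca1_effect_genes": effect1,
        "brca2_effect_genes": effect2,
        "effect_signs": {"BRCA1": signs1.tolist(), "BRCA2": signs2.tolist()},
        "marker_genes": dict(spec.marker_genes),
        "centroids": centroids,
    }
    return expr, ann, truth


def simulate_two_color(
    n_probes: int,
    n_arrays: int,
    params_cy5: NormexpParams = NormexpParams(200.0, 30.0, 1000.0),
    params_cy3: NormexpParams | None = None,
    dye_bias_amplitude: float = 0.0,
    replicate_fraction: float = 0.0,
    unannotated_fraction: float = 0.0,
    log2_fold_changes: np.ndarray | None = None,
    arrays_with_effect: np.ndarray | None = None,
    baseline_ratio_sd: float = 0.0,
    effect_min_signal: float = 0.0,
    shared_channel_noise: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Raw two-color intensities from the signal-plus-background model.

    Each spot draws a common latent signal ``S ~ Exponential(alpha)``; the
    Cy5 channel multiplies it by ``2**log2_fold_change`` (on arrays flagged
    in ``arrays_with_effect``) and by a smooth intensity-dependent dye bias
    ``2**(amplitude * sin(log2(S)/2))``; each channel then adds Gaussian
    background noise on top of a measured background level.  A fraction of
    probes is spotted twice (replicates) and a fraction carries no gene
    symbol.  Returns a long-format batch table plus the ground truth.

    ``baseline_ratio_sd`` adds iid Gaussian biological variation (log2
    units) to every spot's true ratio, emulating tumor-vs-reference
    variability; without it the between-array marginal distributions are
    degenerate and quantile normalization compresses planted effects.
    ``effect_min_signal`` shifts the latent-signal distribution of probes
    carrying a fold change so that planted genes are expressed above
    background (log ratios of near-background spots are intrinsically
    compressed towards zero).

    With ``shared_channel_noise=True`` both channels of a spot share one
    background level and one noise draw (drawn from the Cy5 parameters), so
    that with zero fold change and zero dye bias the channels are literally
    equal — the strict null for the preprocessing pipeline.
    """
    params_cy3 = params_cy3 or params_cy5
    rng = np.random.default_rng(seed)
    fc = np.zeros(n_probes) if log2_fold_changes is None else np.asarray(log2_fold_changes, float)
    if len(fc) != n_probes:
        raise ValueError("log2_fold_changes must have one entry per probe")
    affected = (
        np.ones(n_arrays, dtype=bool)
        if arrays_with_effect is None
        else np.asarray(arrays_with_effect, dtype=bool)
    )

    width = len(str(n_probes))
    probe_ids = [f"P{i:0{width}d}" for i in range(1, n_probes + 1)]
    symbols = np.array([f"GENE{i:0{width}d}" for i in range(1, n_probes + 1)], dtype=object)
    n_unann = int(round(unannotated_fraction * n_probes))
    unannotated = rng.choice(n_probes, size=n_unann, replace=False)
    symbols[unannotated] = ""
    n_rep = int(round(replicate_fraction * n_probes))
    replicated = set(rng.choice(n_probes, size=n_rep, replace=False).tolist())

    # spot layout: replicated probes appear twice on every array
    spot_probe = np.repeat(
        np.arange(n_probes),
        [2 if p in replicated else 1 for p in range(n_probes)],
    )
    n_spots = len(spot_probe)
    frames = []
    for a in range(n_arrays):
        array_id = f"A{a + 1:02d}"
        s = rng.exponential(params_cy3.alpha, size=n_spots)
        s = s + np.where(fc[spot_probe] != 0.0, effect_min_signal, 0.0)
        ratio = np.where(affected[a], fc[spot_probe], 0.0)
        if baseline_ratio_sd > 0:
            ratio = ratio + rng.normal(0.0, baseline_ratio_sd, size=n_spots)
        bias = dye_bias_amplitude * np.sin(np.log2(np.maximum(s, 1.0)) / 2.0)
        s5 = s * 2.0 ** (ratio + bias)
        if shared_channel_noise:
            bg5 = bg3 = np.maximum(rng.normal(100.0, 5.0, size=n_spots), 0.0)
            noise = rng.normal(params_cy5.mu, params_cy5.sigma, size=n_spots)
            fg5 = np.maximum(bg5 + s5 + noise, 0.0)
            fg3 = np.maximum(bg3 + s + noise, 0.0)
        else:
            bg5 = np.maximum(rng.normal(100.0, 5.0, size=n_spots), 0.0)
            bg3 = np.maximum(rng.normal(100.0, 5.0, size=n_spots), 0.0)
            fg5 = np.maximum(
                bg5 + s5 + rng.normal(params_cy5.mu, params_cy5.sigma, size=n_spots), 0.0
            )
            fg3 = np.maximum(
                bg3 + s + rng.normal(params_cy3.mu, params_cy3.sigma, size=n_spots), 0.0
            )
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": np.array(probe_ids, dtype=object)[spot_probe],
                    "gene_symbol": symbols[spot_probe],
                    "array_id": array_id,
                    "fg_cy5": fg5,
                    "bg_cy5": bg5,
                    "fg_cy3": fg3,
                    "bg_cy3": bg3,
                }
            )
        )
    batch = pd.concat(frames, ignore_index=True)
    truth = {
        "params_cy5": params_cy5,
        "params_cy3": params_cy3,
        "log2_fold_changes": fc,
        "arrays_with_effect": affected,
        "annotated_mask": symbols != "",
        "replicated_probes": sorted(probe_ids[p] for p in replicated),
        "probe_ids": probe_ids,
        "gene_symbols": symbols,
    }
    return batch, truth
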