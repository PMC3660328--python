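# brcaness

Identification of *BRCA1*/*BRCA2*-mutated ("BRCAness") breast tumors from
gene-expression profiles.

Tumors arising in germline *BRCA1* and *BRCA2* mutation carriers display
characteristic RNA phenotypes — *BRCA1* tumors are mostly basal-like and
triple-negative, *BRCA2* tumors mostly luminal B. Because carrier status is
strongly associated with the intrinsic molecular subtype, a classifier
trained on a whole cohort can learn subtype membership instead of the
carrier phenotype, and then misclassifies every sporadic tumor of the
carrier-enriched subtype. This package implements a pipeline that builds
carrier-vs-sporadic classifiers while avoiding that confound, for
computational biologists working with two-color expression data or
evaluating BRCAness classification methodology on simulated cohorts:

* **Preprocessing** — normexp background correction (`X = S + B`,
  `S ~ Exp(alpha)`, `B ~ N(mu, sigma^2)`; correction is the posterior mean
  `E[S | X]`), within-array MA-loess, between-array quantile normalization,
  probe-to-gene collapsing.
* **Subtyping** — PAM50-style nearest-centroid assignment under Spearman
  correlation against a user-supplied centroid table; hierarchical
  clustering (Euclidean, complete linkage) of the most variant genes.
* **Receptor status** — ER/PR/HER2 from ESR1/PGR/ERBB2 expression via
  density-valley cutoffs, validated against IHC labels by ROC AUC.
* **Classification** — nested leave-one-out cross-validation: per-fold
  Welch-t gene ranking, inner-loop selection of the gene count (smallest
  count with the highest mean balanced accuracy), linear-kernel SVM with
  Platt-calibrated probabilities reweighted by inverse class priors
  (`p_adj = (p/pi)/((p/pi)+(1-p)/(1-pi))`), threshold 0.5 — overall or
  within a molecular subtype stratum.
* **Signatures** — fixed gene lists derived by full-cohort ranking with
  LOOCV length optimization, transferred to independent cohorts by symbol
  intersection and validated there by LOOCV.
* **Synthetic cohorts** — generators for subtype-structured expression
  matrices with planted carrier effects, bimodal marker genes, and raw
  two-color intensity batches, all with ground truth.

## Worked example

```python
from brcaness.classify import stratified_classify
from brcaness.config import RunConfig
from brcaness.subtype import classify_subtypes
from brcaness.synthetic import CohortSpec, simulate_cohort

expr, annotation, truth = simulate_cohort(CohortSpec(n_genes=2000, seed=7))
annotation["subtype"], _ = classify_subtypes(expr, truth["centroids"])
config = RunConfig(seed=7, gene_count_grid=[5, 10, 25, 50, 100])
result = stratified_classify(expr, annotation, "basal", "BRCA1", config)
print(f"sensitivity {result.sensitivity:.2f}, specificity {result.specificity:.2f}, "
      f"balanced accuracy {result.balanced_accuracy:.2f}, Fisher p {result.fisher_p:.1e}")
```

prints

```
sensitivity 0.95, specificity 1.00, balanced accuracy 0.97, Fisher p 3.7e-07
```

meaning: of the 20 basal-like carrier tumors 19 were assigned a carrier
probability ≥ 0.5 by models that never saw them during gene selection or
training, all 10 basal-like sporadic tumors were called sporadic, and a
carrier/sporadic split this clean would arise by chance with probability
~4·10⁻⁷. The `examples/` directory walks through each capability
(simulation and subtyping, preprocessing, stratified classification,
signature validation, receptor status and clustering); each script prints
the numbers it computes and what they mean.

A thin CLI mirrors the library for shell pipelines:

```bash
brcaness simulate --seed 7 --out cohort/
brcaness classify --matrix cohort/matrix.tsv --annotation cohort/annotation.tsv \
                  --case BRCA1 --stratum basal --out report.json
```

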