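# Methods

## Problem and scope

Breast tumors arising in germline *BRCA1* or *BRCA2* mutation carriers show
characteristic expression phenotypes ("BRCAness"): *BRCA1* tumors are mostly
basal-like and triple-negative, *BRCA2* tumors mostly luminal B. Because the
intrinsic molecular subtype is itself strongly associated with carrier
status, a classifier trained on the whole cohort can separate carriers from
sporadic tumors by learning subtype membership rather than the carrier
phenotype — and then misclassifies every sporadic tumor of the
carrier-enriched subtype. The package implements the complete procedure for
building and validating carrier-vs-sporadic classifiers that avoid this
confound: preprocessing of two-color arrays, subtype assignment,
subtype-stratified nested LOOCV classification, signature derivation, and
cross-dataset validation, together with a synthetic-cohort generator that
provides ground truth for every stage.

## Preprocessing model

Raw spot intensities follow the normexp convolution: observed net intensity
`X = S + B` with signal `S ~ Exponential(alpha)` and background
`B ~ Normal(mu, sigma^2)`. The density is

    f(x) = (1/alpha) exp((mu - x)/alpha + sigma^2/(2 alpha^2))
           * Phi((x - mu)/sigma - sigma/alpha)

Parameters are estimated by direct numerical maximum likelihood
(Nelder–Mead on `(mu, log sigma, log alpha)`, moment-based initialization
using `E[(X-EX)^3] = 2 alpha^3`). The correction replaces `x` by the
posterior mean `E[S | X = x] = mu_s + sigma * phi(z)/Phi(z)` with
`mu_s = x - mu - sigma^2/alpha`, `z = mu_s/sigma`, evaluated in log space;
it is strictly positive and monotone. A constant offset (default 50,
configurable) is added afterwards to stabilize low-intensity log ratios.

Identifiability: at the simulation condition used for validation
(`Exp(1000) + N(200, 30^2)`, n = 10,000 spots) the MLE is unbiased for all
three parameters, but the sampling standard deviation of `sigma` is ~7%
(the background spread is small relative to the exponential signal). The
R reference implementation shows the same spread. Recovery is therefore
asserted per repetition for `mu` and `alpha` and on the mean across ten
repetitions for `sigma`.

Within-array normalization regresses `M = log2 R - log2 G` on
`A = (log2 R + log2 G)/2` with a robust local linear smoother (span 0.3,
4 robustness iterations, configurable) and subtracts the fit. Local
regression is not a projection, so exact idempotency does not hold; a
second application changes an already-normalized array by less than 10% of
the bias the first pass removed, which is the property the tests assert.

Between-array quantile normalization forces a common empirical
distribution via averaged order statistics, with ties assigned the mean of
the reference quantiles they span. It is applied to the individual channel
log-intensities (reconstituted from the loess-normalized M and A and
pooled across channels and arrays), not to the M values: quantile
normalization of M directly compresses genuine log-ratio differences that
are present in only a subset of arrays (a planted 2-fold change loses
6–8% on top of other losses, measured). The M-target variant remains
available (`quantile_target="m"`) for comparison.

Probe collapsing: replicate spots (same probe id) are collapsed to their
per-array median; probes without a gene symbol are dropped; among several
probes for one symbol, the probe with the highest mean Cy5 foreground
intensity is kept (ties broken by lexically first probe id).

## Subtype assignment and receptor status

Subtypes are assigned by nearest centroid under Spearman rank correlation
over the genes shared between matrix and centroid table (median-centering
each gene across samples first; at least 10 shared genes). Ties are broken
in the fixed order basal, her2_enriched, lumA, lumB, normal_like. The
centroid table is an input; the synthetic module generates its own — no
published centroid values are shipped.

ER/PR/HER2 statuses derive from ESR1/PGR/ERBB2 expression (configurable):
the cutoff is the minimum of a Gaussian KDE (Silverman bandwidth) between
its two largest modes; samples at or exactly on the cutoff are positive.
With IHC labels available the expression/IHC ROC AUC is reported (warning
below 0.8), and a unimodal marker falls back to the Youden-J ROC cutoff.

## Nested LOOCV classification

For each held-out sample: (1) genes are ranked by |Welch t| on the
training samples only (ties by lexical symbol; zero-variance genes get
t = 0 and sink); (2) the gene count is chosen by an inner LOOCV over the
training set, re-ranking genes within every inner fold, as the smallest
count achieving the highest mean balanced accuracy; (3) the selected genes
are standardized with training-fold statistics, a linear-kernel soft-margin
SVM (C = 1, not tuned) is trained, and decision values are mapped to
probabilities by a Platt sigmoid; (4) the probability is reweighted by the
inverse training class priors,

    p_adj = (p/pi1) / (p/pi1 + (1-p)/(1-pi1)),   pi1 = n_pos/(n_pos+n_neg),

which is the identity at equal priors and makes 0.5 a prior-free decision
threshold; (5) the sample is called a carrier when `p_adj >= 0.5`.
Performance is summarized as sensitivity, specificity, balanced accuracy
and a two-sided Fisher exact p (probability-mass convention) on the
confusion table. Stratified classification restricts the cohort to one
molecular subtype before the same procedure.

Calibration detail: outer-fold models fit the sigmoid on 3-fold
cross-validated decision values (seeded stratified folds; Platt target
smoothing and a damped Newton solver). The inner selection loop fits the
sigmoid on training decision values directly — tens of thousands of inner
models are fitted per run and the inner loop only needs a ranking of
candidate gene counts, not calibrated probabilities. The SVM itself runs on
the low-level libsvm binding (equivalent to the standard linear-kernel SVC,
asserted in the tests) because per-call overhead, not optimization, would
otherwise dominate the nested loop.

A deliberately leakage-enabled variant (`leaky=True`) performs ranking and
gene-count selection once on the full data including the held-out sample.
It exists purely as a negative control: on effect-free cohorts the nested
procedure averages balanced accuracy 0.5 while the leaky variant exceeds
0.9, demonstrating that the guards are load-bearing.

## Signatures

A fixed signature is derived on a full cohort: genes ranked by |Welch t|
using all samples; for each candidate length the fixed top-N set is
evaluated by LOOCV; the smallest length with the best accuracy wins.
Because the ranking sees every sample, this internal estimate is optimistic
— on cohorts with weak or absent signal it saturates near 1.0, which also
means the derived length collapses to the smallest candidate. Signatures
are therefore labeled training-derived, and the honest evaluation is
external: transfer by symbol intersection (order preserved, at least 10
genes) followed by LOOCV in the independent cohort with the fixed overlap
set and per-dataset standardization (which absorbs cross-platform scale
differences).

## Synthetic cohorts

`simulate_cohort` draws each sample as its subtype centroid plus iid
Gaussian noise on the log2 scale. Defaults: 5,000 genes; centroid spread
0.5; within-subtype noise 0.5; group-by-subtype cells mirroring the study
design (BRCA1 20 basal + 9 lumB + 2 lumA + 2 HER2-enriched; BRCA2 16 lumB
+ 4 lumA + 2 normal-like; sporadic 10/55/48/8/7 across
basal/lumA/lumB/HER2/normal — totals 33/22/128). Carriers are shifted by
±1.0 log2 units on 100 planted genes per carrier group (signs fixed per
gene; the two sets are disjoint from each other and from the markers).
Three marker genes are bimodal by construction (±2.0 around the valley,
high in the subtypes where the receptor is expressed). Ages are drawn
N(43, 8) for carriers and N(61, 12) for sporadic samples, clipped to
[25, 95], echoing the younger onset of carrier disease.

With these defaults the planted per-gene effect is 2 within-subtype
standard deviations, and stratified classification of the basal stratum is
essentially perfect. A weaker regime that lands balanced accuracy in the
0.8–0.9 range simultaneously destroys signature-gene recovery under iid
noise: the internal length-selection rule saturates (see above), so the
derived signature is short, and at weak per-gene effects its precision
drops. No (effect size, noise) pair reproduces simultaneously the study's
accuracy band, its ~100-gene signature lengths, and high planted-gene
recovery; the defaults favor clear effect recovery, and recovery is
measured within the derived signature length.

What the generator deliberately does not model: gene–gene correlation
(signals are iid across genes, so ranked noise tails behave differently
than on real arrays), copy-number or methylation structure, intratumoral
heterogeneity, platform-specific probe effects beyond the two-color noise
model, and missing values. Passing tests demonstrate the pipeline's
statistical machinery is correct and leakage-free under a known generative
model — not that real cohorts reach any particular accuracy.

`simulate_two_color` generates spot-level intensities from the normexp
convolution with a shared latent signal per spot, an optional smooth
multiplicative dye bias on Cy5 (`2^(a * sin(log2 S / 2))`), optional
per-spot biological log-ratio variation, replicate spots and unannotated
probes. `shared_channel_noise=True` makes both channels share one noise
realization — the strict null in which the final matrix must be exactly
zero. Planted fold changes are sign-balanced in the validation experiments
so they do not drag the loess fit or the quantile reference.

## Confounding experiment

The subtype-confound reproduction uses a purpose-built cohort in which
carriers concentrate in the basal-like subtype (20 basal + 2 lumA) against
sporadic controls that are mostly luminal (10 basal + 40 lumA), with a
carrier effect weak enough that cohort-level gene ranking is dominated by
subtype-discriminating genes. The general (unstratified) classifier then
labels basal tumors as carriers — its specificity among basal sporadic
tumors collapses — while the stratified classifier, free of between-subtype
variance, recovers the carrier signal. Effect and spread for this cohort
are chosen to put the experiment robustly in that regime and are documented
in `brcaness.experiments`.

## Problem sizes and determinism

Validation experiments run on one core in minutes: null calibration uses
twenty 60-sample, 2,000-gene cohorts with gene-count grid {5, 10, 25, 50};
effect recovery uses the full default cohort with grids up to 150;
preprocessing recovery uses 10,000-probe, 6-array batches; subtype recovery
uses twenty 200-sample draws at noise sd 0.25. Every generator and every
cross-validation loop is a pure function of its seed (per-fold seeds are
derived deterministically), so identical inputs and seeds give
byte-identical results.

## Known limitations

* The gene-count grid, SVM cost, loess span and normexp offset are fixed
  defaults, not tuned; the published analyses this mirrors do not state
  them either, so agreement at that level is structural, not numeric.
* Quantile normalization (either target) still slightly compresses
  differential signal concentrated in distribution tails.
* The probability calibration follows one concrete reading (Platt sigmoid
  on cross-validated decision values); platforms that calibrate differently
  will produce different probabilities near the 0.5 threshold even with
  identical rankings.
* Fisher p-values are exact but the probability-mass two-sided convention
  differs from doubling-the-one-tail conventions used by some software.
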