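"""Simulate a study-sized cohort and assign intrinsic molecular subtypes.

Builds the default synthetic cohort (33 BRCA1 / 22 BRCA2 / 128 sporadic
tumors, 5,000 genes, five subtype clusters), then calls subtypes by nearest
centroid under Spearman correlation and tests carrier/subtype association.
"""

from brcaness.subtype import classify_subtypes, subtype_enrichment
from brcaness.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(seed=42)
expr, annotation, truth = simulate_cohort(spec)
print(f"cohort: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(annotation.group.value_counts().to_string())

calls, correlations = classify_subtypes(expr, truth["centroids"])
recovery = (calls == annotation.subtype).mean()
print(f"\nsubtype calls recover the generating subtype for {recovery:.1%} of samples")

annotation = annotation.assign(subtype=calls)
enrichment = subtype_enrichment(annotation)
top = enrichment.nsmallest(3, "fisher_p")
print("\nstrongest group/subtype associations (two-sided Fisher exact):")
for row in top.itertuples():
    print(f"  {row.group:8s} x {row.subtype:13s} p = {row.fisher_p:.1e}")
# BRCA1 tumors concentrate in the basal-like subtype and BRCA2 in luminal B
# by construction, so those two pairs should dominate this table.
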