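"""Diagnosis-by-age interaction on gradient maps with cluster correction.

Fits the voxelwise GLM gradient ~ 1 + diagnosis + age + diagnosis*age +
sex + site, converts the interaction F map to equivalent z, forms
clusters at z > 2.3 (26-neighbour connectivity) and corrects them by
Freedman-Lane max-cluster-size permutation, then runs the four pairwise
post hoc rank tests on the cluster means.
"""

import numpy as np

import ccgrad as cg

cohort = cg.build_cohort(cg.CohortConfig(mode="connectivity", seed=2))
maps, _, _ = cg.cohort_gradients(cohort)
df = cohort.to_dataframe()
design = cg.design_from_table(df)

clusters = cg.permutation_cluster(
    maps, design, term="interaction", geometry=cohort.mask_ctx,
    cluster_z=2.3, n_perm=1000, seed=2,
)
print("interaction clusters (size, corrected p):")
for c in clusters.clusters:
    print(f"  {c['size']:4d} voxels   p = {c['corrected_p']:.4f}")

truth = cohort.truth["HC-child"]
planted = set(truth.shifted_sets["DMN"]) | set(truth.shifted_sets["VN"])
for i, c in enumerate(clusters.significant()):
    hit = len(set(c["voxels"]) & planted)
    print(f"cluster {i}: {hit}/{c['size']} voxels inside the planted "
          "DMN/VN shift sets")

posthoc = cg.posthoc_cluster_comparisons(maps, clusters, df)
sig = posthoc[posthoc.cluster.isin(
    [i for i, c in enumerate(clusters.clusters) if c["corrected_p"] < 0.05]
)]
print("\npost hoc rank tests on cluster means (first significant cluster):")
first = sig[sig.cluster == sig.cluster.iloc[0]]
for _, row in first.iterrows():
    print(f"  {row.group1:16s} vs {row.group2:16s} U = {row.u:5.0f}  "
          f"p = {row.p:.2e}")
print(
    "\nU above n1*n2/2 = 200 means the first group's cluster means are\n"
    "higher.  The interaction is driven by the healthy developmental\n"
    "divergence that is absent in patients; the planted child compression\n"
    "also separates the child groups."
)
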