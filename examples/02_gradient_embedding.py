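"""From voxel time series to an aligned principal functional gradient.

Runs the full per-subject chain on a small timeseries-mode cohort:
temporal cleaning -> cortex x cerebellum Pearson correlation -> Fisher Z
-> row-wise top-10% sparsification -> cosine affinity -> diffusion-map
embedding (alpha = 0.5) -> Procrustes alignment to the group template,
then checks how well gradient 1 recovers the planted voxel positions.
"""

import numpy as np
from scipy.stats import spearmanr

import ccgrad as cg

config = cg.CohortConfig(mode="timeseries", n_per_cell=3, seed=1)
cohort = cg.build_cohort(config)

maps, template, gradient_sets = cg.cohort_gradients(cohort)

lam = template.eigenvalues[:3]
ve = template.variance_explained[:3]
print("template eigenvalues (first 3):", np.round(lam, 4))
print("variance explained (first 3): ", np.round(ve, 4))
print("Gradient 1 explains the largest share; it is the principal gradient.")

rhos = [
    abs(spearmanr(m, cohort.truth[rec.cell].u).statistic)
    for m, rec in zip(maps, cohort.records)
]
print(f"\nmean |Spearman rho| of aligned gradient 1 vs planted positions: "
      f"{np.mean(rhos):.4f}")
print("Values near 1 mean the embedding orders voxels along the planted")
print("unimodal-to-transmodal hierarchy almost perfectly.")

dmn = cg.synthetic.network_indices(cohort.truth["HC-child"].network_label, "DMN")
vn = cg.synthetic.network_indices(cohort.truth["HC-child"].network_label, "VN")
print(f"\ngroup-template gradient 1: DMN mean {template.gradient(1)[dmn].mean():+.2f}, "
      f"VN mean {template.gradient(1)[vn].mean():+.2f}")
print("The DMN sits at the positive pole and the visual network at the")
print("negative pole, the conventional orientation of the principal gradient.")
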