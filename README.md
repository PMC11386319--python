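# ccgrad — cerebro-cerebellar functional-gradient analysis

`ccgrad` is a tested, reusable pipeline for studying the macroscale
functional hierarchy that links the cerebral cortex and the cerebellum in
resting-state fMRI, and how that hierarchy is *compressed* in clinical
groups — the phenomenon reported for children and adolescents with ADHD.
It is aimed at researchers who want a desk-scale, fully reproducible
implementation of the gradient-compression analysis: every stage can be run
on a synthetic cohort in which the ground truth is planted, so the whole
chain — connectivity, embedding, alignment, statistics — is testable.

## The method

For each subject, the voxel-level cross-structure connectivity matrix
**C** (cortex × cerebellum Pearson r) is Fisher-Z transformed,
row-sparsified to its top 10% of entries, and turned into a cosine
affinity **A**, with `A_ik = x_i·x_k / (‖x_i‖‖x_k‖)` over sparse
connectivity profiles. The principal functional gradient is the leading
non-trivial component of the anisotropic diffusion-map embedding of **A**:

1. `W = D^(−α) A D^(−α)` with `D = diag(A·1)` and `α = 0.5`
   (Fokker–Planck normalization; `α = 0` is the graph Laplacian,
   `α = 1` Laplace–Beltrami);
2. `P = D′^(−1) W`, eigendecomposed through the symmetric conjugate
   `S = D′^(−1/2) W D′^(−1/2)`;
3. eigenvectors are mapped to `ψ_m = D′^(−1/2) v_m`, normalized so the
   trivial `ψ_0 ≡ 1`, and scaled by `λ_m/(1−λ_m)` (diffusion time 0).

Per-subject embeddings are aligned to a group template (embedding of the
mean sparse profile matrix) by orthogonal Procrustes rotation, oriented so
the default-mode network (DMN) sits at the positive pole. Group inference
is a voxelwise GLM `gradient ~ diagnosis × age + sex + site` with
Freedman–Lane max-cluster-size permutation correction (cluster-forming
z > 2.3 for F maps, |z| > 2.5 for t maps), post hoc Mann–Whitney U tests on
cluster means, and two compression statistics: distribution-shift U tests
on voxel pools per network, and the **full range** `FR = max(g1) − min(g1)`
per subject, compared between groups after sex/site residualization. The
same code path embeds the transposed matrix for the cerebellar-side
gradients, and Pearson correlations link region gradients to per-site
rescaled symptom scores.

The synthetic cohort plants all of this: a latent voxel position in
[−1, 1] shaping cross-structure connectivity, a diagnosis × age design in
which healthy adolescents' DMN/VN poles diverge while patients' positions
are compressed by a factor κ, two scanner sites, and symptom scores
negatively coupled to a DMN sub-region.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/04_compression_clinical.py` prints:

```
DMN: pooled mean diff (ADHD-HC) = -17.404, U = 0, p = 0.00e+00
VN: pooled mean diff (ADHD-HC) = +14.487, U = 2958400, p = 0.00e+00
The DMN pool shifts down and the VN pool shifts up in patients:
both poles move toward the centre - gradient compression.

FR mean: ADHD 34.9, HC 69.0 (ratio 0.51)
  FR comparison, children   : U =     0, p = 6.80e-08
  FR comparison, adolescents: U =     0, p = 6.80e-08
  FR comparison, all        : U =     0, p = 1.44e-14

clinical: r = -0.812 (p = 6.40e-20) between the DMN symptom-region
gradient and rescaled hyperactivity/impulsivity - the planted
negative coupling is recovered.
```

The DMN pool (positive pole) moves down and the visual pool (negative
pole) moves up in the patient group — both poles toward the centre — and
the per-subject gradient range is significantly smaller in every age
stratum: the planted compression is recovered end to end, as is the
planted negative symptom coupling.
`examples/02_gradient_embedding.py` shows the embedding itself: the
aligned principal gradient orders voxels along the planted hierarchy with
mean |Spearman ρ| = 0.9989.

A thin CLI wraps the same stages for shell use:

```bash
ccgrad simulate --out cohort/ --seed 1
ccgrad run-all  --out run/    --seed 1     # simulate + all analysis stages
ccgrad gradients --in cohort/ --out grad/ --density 0.1 --alpha 0.5 --k 10
```

Every table is written as TSV with a JSON sidecar recording the exact
parameters and seeds; `run-all` writes a manifest sufficient to re-run
bit-identically.

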