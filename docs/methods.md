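# Methods

This note documents the models, conventions and design choices behind
`ccgrad`, in the spirit of the methods documentation of the established
gradient toolboxes.

## Pipeline model

The object of study is the cross-structure connectome: for each subject a
cortex × cerebellum matrix of Pearson correlations between cleaned voxel
time series (or, in fast mode, a directly planted correlation matrix).
The analysis assumes that a voxel's *connectivity profile* — its row of
the cross-structure matrix — varies smoothly along a latent functional
hierarchy, and estimates that hierarchy per subject as the principal
component of a diffusion-map embedding of profile similarity.

Stages and their contracts:

1. **Temporal cleaning** (`preprocess`): per-voxel linear detrending,
   OLS confound regression (residuals orthogonal to all regressors), and
   zero-phase band-pass filtering at 0.01–0.1 Hz. The filter is a
   2nd-order Butterworth applied forward–backward (scipy `filtfilt`,
   odd-reflection padding), chosen as a standard design with a testable
   frequency-response contract: a 0.05 Hz sinusoid at TR = 2 s is
   preserved within 10%, a 0.2 Hz sinusoid attenuated by ≥ 80%, and DC
   rejected. All three operations are linear. They are *not* jointly
   idempotent to machine precision: the soft pass band of a realizable
   filter attenuates edge-of-band energy on every application (≈ 19%
   relative norm on white noise), so only the projection steps (detrend,
   regression) are exactly idempotent. Upstream volume preprocessing
   (motion correction, normalization, confound extraction) is assumed
   done; the pipeline accepts an arbitrary confound matrix.

2. **Connectivity** (`connectome`): Pearson r (zero-variance voxels are
   an error naming the voxel indices), Fisher Z with |r| clamped to
   1 − 1e−7, then row-wise sparsification keeping the top
   `ceil(0.10 · n_cols)` entries per row. Ranking is on the signed Z
   values (order-equivalent to ranking r); ties at the cutoff keep the
   lower column index, deterministically. Surviving negative values are
   clamped to zero so the affinity is nonnegative and the Markov
   normalization of the embedding is well defined; with top-10%
   retention, negative survivors are rare. Row-wise (not global)
   thresholding keeps every voxel's profile comparable.

3. **Embedding** (`gradients`): cosine affinity of the sparse profiles,
   then the anisotropic diffusion map with α = 0.5 and k = 10 components.
   Numerical conventions, all fixed for bit-reproducibility:
   - dense symmetric eigensolver for n ≤ 2000, iterative solver with a
     fixed start vector above;
   - eigenvectors mapped to Markov eigenvectors via `D′^(−1/2)` and
     normalized so the trivial eigenvector is identically 1 (`ψ0 = 1`,
     the convention of the standard diffusion-mapping toolboxes). This
     fixes the otherwise arbitrary component scale and makes the
     embedding exactly α-independent on constant-degree graphs;
   - diffusion-time-0 scaling `λ/(1−λ)`;
   - per-component sign fixed so the largest-magnitude entry is positive;
   - variance explained `λ_m² / Σ λ_j²` over the non-trivial spectrum
     (the λ²-based definition; the λ-based one differs only by a
     monotone reparameterization and is not used);
   - asymmetric, negative, or disconnected affinities (second eigenvalue
     within 1e−10 of 1) are errors, not warnings.

4. **Template and alignment**: the group template is the embedding of
   the element-wise mean of the subjects' sparse profile matrices —
   deterministic and order-independent, unlike iterative
   mean-of-aligned-gradients schemes. Its gradient 1 is flipped if
   needed so the DMN mean is positive (transmodal pole positive).
   Subjects are aligned by orthogonal Procrustes (`R = UVᵀ` from the SVD
   of `GᵀT`; rotation/reflection only, no centering or scaling), which
   preserves the Frobenius norm exactly. Alignment is done in the full
   k = 10 component space (more stable than aligning gradient 1 alone);
   only gradient 1 is analyzed downstream. The cerebellar-side analysis
   embeds the transposed matrix through the same code path.

5. **Group statistics** (`stats`): voxelwise OLS on
   `[1, D, A, D·A, sex, site]` with ±1 effect coding (interaction
   coefficient = half the difference-of-differences; orthogonal main
   effects in balanced designs). The interaction F is the squared t of
   the D·A coefficient, df (1, n − p). Cluster correction is
   Freedman–Lane max-cluster-size permutation: residualize on the
   reduced model, permute residual rows, refit, record the maximum
   supra-threshold cluster size; corrected
   p = (1 + #{null ≥ observed}) / (1 + n_perm). Cluster forming uses the
   equivalent-z maps (one-tailed z > 2.3 for F, two-tailed |z| > 2.5 for
   t) and 26-neighbour 3-D connectivity. Parametric random-field
   correction was deliberately replaced: it requires the smoothness of
   real volumetric data and a specific estimator, while permutation is
   exact under exchangeability and testable at desk scale; the
   substitution and thresholds are recorded in every `ClusterResult`.
   Voxels with numerically zero residual variance get t = ±inf (nonzero
   coefficient) or 0, rather than float garbage.
   Mann–Whitney U uses the `#{x > y} + ½·ties` convention (declared
   explicitly because published U values do not identify the
   convention); p is exact by enumeration when n1 + n2 ≤ 20 without
   ties, else a tie- and continuity-corrected normal approximation.
   Post hoc tests compare subject-level cluster means across the four
   diagnosis/age pairs, without covariate adjustment (a residualized
   variant is available via `compression.residualize`).

6. **Compression** (`compression`): histograms and shift tests operate
   on voxel pools concatenated across subjects within group — pool size
   n_subjects × n_network_voxels — matching the magnitude of published
   pooled U statistics; histograms use 100 bins (fewer if the pool is
   smaller) over the shared min/max range of the compared groups and
   integrate to exactly 1. FR = max − min of the subject's gradient-1
   map (translation invariant, positively scale equivariant). Group FR
   comparisons residualize on sex and site once, then run U tests within
   children, within adolescents, and pooled: a declared substitute for
   "controlling for sex and site" in a rank test, recorded in output
   metadata. Symptom subscales are rescaled to [0, 1] by the within-site
   maximum before Pearson correlation; both uncorrected and
   Benjamini–Hochberg p-values are reported.

## The synthetic cohort

The generator's role is to plant, at desk scale, exactly the structure
the analysis is meant to detect.

- **Latent positions.** Each voxel gets a position in [−1, 1]. Seven
  networks with archetype positions VN −0.9, SMN −0.6, DAN −0.3,
  VAN −0.1, Limbic +0.2, FPN +0.5, DMN +0.9 (matching the qualitative
  unimodal→transmodal ordering; exact values are free parameters) occupy
  contiguous segments of the axis whose edges are archetype midpoints,
  and positions are uniform within segment. The continuous tiling is
  deliberate: real macroscale hierarchies are continuous, and a gapped
  (multimodal) position distribution makes the top-10% sparse profile
  graph disconnect between the poles at a few hundred voxels, which the
  embedding rightly refuses. For the same reason the developmental shift
  (below) is a linear taper — zero at the segment's inner edge, 2δ at
  the pole, mean δ — rather than a block translation that would tear the
  continuum. Networks are laid out as contiguous strips on a
  1-voxel-thick sheet, so planted effects form spatial clusters.
- **Design.** Base positions are drawn once per seed; cells differ only
  by deterministic adjustments: healthy adolescents' DMN shifts up and
  VN down by mean δ = 0.15 (poles diverge with development); all patient
  positions are multiplied by κ = 0.7 and patients lack the
  developmental shift. Compression is planted in patient *children* as
  well — the generator follows the FR findings, which show reduced range
  in children, even though the cluster-level child contrast in the
  source analysis was null; this tension is inherited from the study
  design, not resolved here, and it means post hoc child contrasts on
  synthetic cohorts are genuinely non-null.
- **Data modes.** `timeseries` drives cortex and cerebellum from 12
  shared latent AR(1) sources (lag-1 coefficient 0.3) through
  row-normalized Gaussian-kernel loadings (bandwidth 0.35), plus white
  observation noise, so cross-correlation decays with position distance;
  `connectivity` plants `z = exp(−Δ²/(2·0.5²))` plus Gaussian noise
  directly and is used for replicate-heavy power and calibration
  experiments. `noise_sigma = 0.1` (10% of the kernel amplitude) is the
  default observation-noise SD in both modes.
- **Covariates and symptoms.** Two sites with a 1.1× connectivity-scale
  difference and random unequal allocation; sex Bernoulli(0.65 male), no
  planted sex effect. Hyperactivity/impulsivity and inattention are
  `intercept − 1.0 × (DMN symptom-region mean position) + 0.5·ε`,
  clipped at zero, with patient intercept 3.5 vs 2.0 — patients score
  higher, and scores are negatively coupled to the region's gradient.
- **What it does not emulate:** hemodynamics, spatial autocorrelation of
  real BOLD, head motion, scanner drift, or realistic anatomical
  geometry. Passing tests therefore demonstrate the *computational*
  correctness and statistical calibration of the pipeline, not its
  robustness to acquisition artifacts.

## Problem sizes and calibration

Default synthetic scale: 300 cortical and 120 cerebellar voxels, 150
time points, 20 subjects per cell. Replicate experiments (null
calibration over 100 cohorts, power over 25) use the fast connectivity
mode with 200 permutations per cluster test; single-cohort analyses use
1000 permutations. Under the no-effect configuration (κ = 1, δ = 0) the
FR comparison and the cluster-corrected interaction test both reject at
close to the nominal 5% over 100 replicate cohorts, and under the
default planted effects the FR reduction, both pole shifts, and a
cluster overlapping the planted voxels are detected in ≥ 80% of
replicates.

A note on effect scale: because the embedding normalizes components
(`ψ0 = 1`, unit-free), planted position compression acts on the measured
gradient mainly through the leading eigenvalue's `λ/(1−λ)` scale, which
shrinks when connectivity profiles homogenize. The measured FR ratio in
patients is therefore *stronger* than κ itself (≈ 0.5 at default noise
in connectivity mode, ≈ 0.7 in timeseries mode); the FR comparison tests
ordering, not the value of κ, so this amplification is benign.

## Degenerate inputs and edge cases

Zero-variance voxels: error in correlation, missing-with-warning in
one-sample t. All-zero sparse profiles: error naming the rows. Tiny
cohorts in which a covariate is constant (e.g. all male) drop that
covariate from the design; covariates collinear with the design by
chance trigger a warning and a covariate-free refit in the orchestrator
(the strict `DesignInfo` constructor still errors). Histogram bin count
is capped at the pool size. Single-subject sites rescale that subject's
score to 1.0. Rank-deficient Procrustes cross-products warn and proceed
with the convention singular vectors.

## Known limitations

- The group template is the embedding of the mean profile matrix; with
  severely heterogeneous subjects a mean-profile template can sit far
  from every individual. At the planted heterogeneity this is not a
  problem (alignment recovers planted order at |ρ| ≥ 0.99).
- Two-tailed t-map clusters are formed on |z|, so adjacent positive and
  negative effects can merge into one cluster.
- Exact Mann–Whitney enumeration is only used up to n1 + n2 ≤ 20; the
  normal approximation beyond that is standard but approximate.
- The permutation scheme assumes exchangeable errors under the reduced
  model; heteroscedasticity across sites beyond the modeled scale factor
  would violate it.
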