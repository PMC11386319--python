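"""Gradient-compression metrics and clinical correlation.

Pools voxel-level gradient values per network across subjects to test
distribution shifts (Mann-Whitney U on the pooled samples), compares
the per-subject full range (FR, max minus min of the gradient map)
between groups after sex/site residualization, and correlates the
DMN symptom-region gradient with per-site-rescaled symptom scores.
"""

import numpy as np
from scipy.stats import pearsonr

import ccgrad as cg

cohort = cg.build_cohort(cg.CohortConfig(mode="connectivity", seed=3))
maps, _, _ = cg.cohort_gradients(cohort)
df = cohort.to_dataframe()
truth = cohort.truth["HC-child"]
diag = df.diagnosis.to_numpy()

for net, lab in (("DMN", 7), ("VN", 1)):
    pa = cg.pooled_network_values(maps[diag == "ADHD"], truth.network_label, lab)
    ph = cg.pooled_network_values(maps[diag == "HC"], truth.network_label, lab)
    res = cg.shift_test(pa, ph)
    print(f"{net}: pooled mean diff (ADHD-HC) = {pa.mean() - ph.mean():+7.3f}, "
          f"U = {res.u_statistic:.0f}, p = {res.p_value:.2e}")
print("The DMN pool shifts down and the VN pool shifts up in patients:")
print("both poles move toward the centre - gradient compression.")

fr = np.array([cg.full_range(m) for m in maps])
tests = cg.compare_fr(fr, df)
print(f"\nFR mean: ADHD {fr[diag == 'ADHD'].mean():.1f}, "
      f"HC {fr[diag == 'HC'].mean():.1f} "
      f"(ratio {fr[diag == 'ADHD'].mean() / fr[diag == 'HC'].mean():.2f})")
for stratum, res in tests.items():
    print(f"  FR comparison, {stratum:11s}: U = {res.u_statistic:5.0f}, "
          f"p = {res.p_value:.2e}")
print("Patients' gradient range is roughly halved: the planted position")
print("compression (kappa = 0.7) is amplified because the embedding's")
print("eigenvalue scale also shrinks when connectivity profiles homogenize.")

rescaled = cg.rescale_symptoms(df)
x = maps[:, truth.symptom_region].mean(axis=1)
r, p = pearsonr(x, rescaled.hyperactivity_impulsivity)
print(f"\nclinical: r = {r:.3f} (p = {p:.2e}) between the DMN symptom-region")
print("gradient and rescaled hyperactivity/impulsivity - the planted")
print("negative coupling is recovered.")
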