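"""End-to-end orchestration: synthetic cohort (or loaded data) ->
cleaning -> connectivity -> gradients -> group statistics ->
compression/clinical analysis, with a run manifest for reproducibility.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compression as comp
from . import connectome as conn
from . import gradients as grad
from . import io as ccio
from . import preprocess as prep
from . import stats as gstats
from .synthetic import CohortConfig, CohortTable, build_cohort, network_indices


@dataclass
class PipelineConfig:
    """Parameters of every pipeline stage, with the study defaults."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    low_hz: float = 0.01
    high_hz: float = 0.1
    density: float = 0.10
    alpha: float = 0.5
    k: int = 10
    cluster_z_interaction: float = 2.3
    cluster_z_main: float = 2.5
    n_perm: int = 1000
    n_bins: int = 100
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    outputs: dict
    started: str
    finished: str
    package_version: str


def subject_z_matrix(cohort: CohortTable, subject_id: str,
                     low_hz: float = 0.01, high_hz: float = 0.1) -> np.ndarray:
    """Fisher-Z cortex x cerebellum connectivity for one subject.

    In timeseries mode the raw series are cleaned (detrend -> band-pass;
    the synthetic cohort has no external confounds) and correlated; in
    connectivity mode the stored r matrix is Fisher-Z transformed.
    """
    handle = cohort.data[subject_id]
    if cohort.config.mode == "timeseries":
        ts_ctx, ts_cb = handle
        tr = cohort.config.tr
        c_ctx = prep.clean(prep.VoxelTimeSeries(ts_ctx, tr, "cortex"),
                           low_hz=low_hz, high_hz=high_hz)
        c_cb = prep.clean(prep.VoxelTimeSeries(ts_cb, tr, "cerebellum"),
                          low_hz=low_hz, high_hz=high_hz)
        r = conn.cross_correlation(c_ctx.data, c_cb.data, "cortex", "cerebellum")
    else:
        r = conn.ConnectivityMatrix(values=handle, source_mask_id="cortex",
                                    target_mask_id="cerebellum", scale="r")
    return conn.fisher_z(r).values


def cohort_gradients(cohort: CohortTable, structure: str = "cortex",
                     density: float = 0.10, alpha: float = 0.5, k: int = 10,
                     low_hz: float = 0.01, high_hz: float = 0.1):
    """Aligned principal-gradient maps for every subject.

    ``structure`` selects the embedded side: ``"cortex"`` embeds cortical
    voxels by their cerebellar connectivity profiles, ``"cerebellum"``
    embeds the transposed matrix.  Returns ``(maps, template, gradient_sets)``
    where maps is subjects x voxels (gradient 1, Procrustes-aligned to
    the group template built from the mean sparse profile matrix).
    """
    if structure not in ("cortex", "cerebellum"):
        raise ValueError(f"unknown structure {structure!r}")
    truth0 = next(iter(cohort.truth.values()))
    if structure == "cortex":
        dmn = network_indices(truth0.network_label, "DMN")
    else:
        dmn = network_indices(truth0.network_label_cb, "DMN")

    profiles = []
    for rec in cohort.records:
        z = subject_z_matrix(cohort, rec.id, low_hz=low_hz, high_hz=high_hz)
        if structure == "cerebellum":
            z = z.T
        m = conn.ConnectivityMatrix(values=z, scale="z")
        profiles.append(conn.sparsify_rows(m, density=density))

    template = grad.build_template(profiles, dmn_indices=dmn, alpha=alpha, k=k)
    gradient_sets = []
    maps = np.empty((len(profiles), profiles[0].values.shape[0]))
    for i, sp in enumerate(profiles):
        emb = grad.diffusion_embedding(grad.cosine_affinity(sp), alpha=alpha, k=k)
        aligned = grad.procrustes_align(emb, template)
        gradient_sets.append(aligned)
        maps[i] = aligned.gradient(1)
    return maps, template, gradient_sets


def analyze_cohort(cohort: CohortTable, config: PipelineConfig | None = None,
                   structures=("cortex", "cerebellum")) -> dict:
    """Run gradients + statistics + compression on an in-memory cohort.

    Returns a nested dict of results keyed by structure, plus the
    subjects table augmented with rescaled symptom scores.
    """
    cfg = config or PipelineConfig(cohort=cohort.config, seed=cohort.config.seed)
    df = cohort.to_dataframe()
    try:
        design = gstats.design_from_table(df)
    except ValueError as exc:
        # tiny cohorts can make covariates collinear with the design by chance
        warnings.warn(f"dropping covariates from the GLM design: {exc}",
                      RuntimeWarning)
        design = gstats.design_from_table(df, covariates=False)
    truth0 = next(iter(cohort.truth.values()))
    results: dict = {"subjects": df, "config": cfg}

    for structure in structures:
        maps, template, _ = cohort_gradients(
            cohort, structure=structure, density=cfg.density, alpha=cfg.alpha,
            k=cfg.k, low_hz=cfg.low_hz, high_hz=cfg.high_hz,
        )
        geometry = cohort.mask_ctx if structure == "cortex" else cohort.mask_cb
        labels = (truth0.network_label if structure == "cortex"
                  else truth0.network_label_cb)

        cell = (df["diagnosis"] + "-" + df["age_group"]).to_numpy()
        t_maps = {c: gstats.one_sample_t(maps[cell == c]) for c in np.unique(cell)}
        glm = gstats.glm_interaction(maps, design)
        clusters = gstats.permutation_cluster(
            maps, design, "interaction", geometry,
            cluster_z=cfg.cluster_z_interaction, n_perm=cfg.n_perm, seed=cfg.seed,
        )
        posthoc = (gstats.posthoc_cluster_comparisons(maps, clusters, df)
                   if clusters.clusters else pd.DataFrame())

        diag = df["diagnosis"].to_numpy()
        pools = {}
        shift = {}
        from .synthetic import NETWORK_NAMES
        for net in ("DMN", "VN", "ALL"):
            lab = None if net == "ALL" else NETWORK_NAMES.index(net) + 1
            pool_adhd = comp.pooled_network_values(maps[diag == "ADHD"], labels, lab)
            pool_hc = comp.pooled_network_values(maps[diag == "HC"], labels, lab)
            lo = min(pool_adhd.min(), pool_hc.min())
            hi = max(pool_adhd.max(), pool_hc.max())
            # small cohorts cannot fill the default 100 bins
            bins = min(cfg.n_bins, pool_adhd.size, pool_hc.size)
            pools[net] = {
                "ADHD": comp.histogram_density(pool_adhd, bins, (lo, hi),
                                               group="ADHD", network=net),
                "HC": comp.histogram_density(pool_hc, bins, (lo, hi),
                                             group="HC", network=net),
            }
            shift[net] = {
                "test": comp.shift_test(pool_adhd, pool_hc),
                "mean_diff": float(pool_adhd.mean() - pool_hc.mean()),
            }

        fr = np.array([comp.full_range(m) for m in maps])
        fr_tests = comp.compare_fr(fr, df)

        results[structure] = {
            "maps": maps,
            "template": template,
            "one_sample_t": t_maps,
            "glm": glm,
            "clusters": clusters,
            "posthoc": posthoc,
            "histograms": pools,
            "shift_tests": shift,
            "fr": fr,
            "fr_tests": fr_tests,
        }

    # clinical correlations on the cortical symptom region
    rescaled = comp.rescale_symptoms(df)
    region_means = {
        "DMN_symptom_region": results["cortex"]["maps"][:, truth0.symptom_region].mean(axis=1)
    }
    results["clinical"] = comp.clinical_correlation(region_means, rescaled)
    results["subjects_rescaled"] = rescaled
    return results


def _cluster_table(cr: gstats.ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cluster": i, "size": c["size"], "peak_stat": c["peak_stat"],
             "corrected_p": c.get("corrected_p", np.nan)}
            for i, c in enumerate(cr.clusters)
        ]
    )


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Simulate, analyze, and write every artifact to ``out_dir``."""
    from . import __version__

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = build_cohort(config.cohort)
    ccio.save_cohort(cohort, out / "cohort")
    results = analyze_cohort(cohort, config)
    outputs = write_results(results, cohort, out, config)

    manifest = RunManifest(
        config=asdict(config),
        outputs=outputs,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        package_version=__version__,
    )
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2, default=ccio._jsonify) + "\n"
    )
    return manifest


def write_results(results: dict, cohort: CohortTable, out: Path,
                  config: PipelineConfig) -> dict:
    """Write tables/volumes for an analyzed cohort; returns path->digest."""
    out = Path(out)
    params = asdict(config)
    outputs = {}

    def _table(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        ccio.write_sidecar(path, params)
        outputs[name] = ccio.file_digest(path)

    for structure in ("cortex", "cerebellum"):
        if structure not in results:
            continue
        res = results[structure]
        geom = cohort.mask_ctx if structure == "cortex" else cohort.mask_cb
        ccio.write_masked_volume(res["maps"], geom,
                                 out / f"gradient1_{structure}.nii.gz")
        outputs[f"gradient1_{structure}.nii.gz"] = ccio.file_digest(
            out / f"gradient1_{structure}.nii.gz")
        ccio.write_masked_volume(res["glm"]["F_interaction"].statistic, geom,
                                 out / f"F_interaction_{structure}.nii.gz")
        _table(_cluster_table(res["clusters"]), f"clusters_{structure}.tsv")
        if len(res["posthoc"]):
            _table(res["posthoc"], f"posthoc_{structure}.tsv")
        fr_df = pd.DataFrame({
            "id": [r.id for r in cohort.records],
            "structure": structure,
            "fr": res["fr"],
        })
        _table(fr_df, f"fr_{structure}.tsv")
        fr_rows = [
            {"stratum": k, "u": v.u_statistic, "p": v.p_value,
             "n1": v.n1, "n2": v.n2, "method": v.method}
            for k, v in res["fr_tests"].items()
        ]
        _table(pd.DataFrame(fr_rows), f"fr_tests_{structure}.tsv")
        shift_rows = [
            {"network": net, "u": d["test"].u_statistic, "p": d["test"].p_value,
             "mean_diff_ADHD_minus_HC": d["mean_diff"]}
            for net, d in res["shift_tests"].items()
        ]
        _table(pd.DataFrame(shift_rows), f"shift_tests_{structure}.tsv")

    clin_rows = [
        {"region": c.region, "score": c.score, "r": c.pearson_r,
         "p": c.p_value, "p_adjusted": c.p_adjusted, "n": c.n}
        for c in results["clinical"]
    ]
    _table(pd.DataFrame(clin_rows), "clinical_correlations.tsv")
    _table(results["subjects_rescaled"], "subjects_rescaled.tsv")
    return outputs
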