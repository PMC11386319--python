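"""Voxelwise group inference on gradient maps.

One-sample t maps per group, the 2x2 diagnosis-by-age GLM with sex/site
covariates, permutation-based cluster correction (Freedman-Lane scheme,
max-cluster-size statistic), Mann-Whitney U tests, and per-cluster post
hoc comparisons.

Cluster correction replaces parametric random-field correction: the
observed statistic map is converted to an equivalent-z map, thresholded
(one-tailed z > 2.3 for F maps, two-tailed |z| > 2.5 for t maps by
default), clusters are formed under 26-neighbour connectivity, and the
null distribution of the maximum cluster size is built by permuting
reduced-model residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as spstats

from .masks import MaskGeometry

TERMS = ("interaction", "diagnosis", "age")

#: 26-neighbour connectivity structure for 3-D cluster formation.
CONN_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DesignInfo:
    """Effect-coded 2x2 design with covariates.

    Diagnosis and age are coded +/-1 (ADHD = +1, adolescent = +1) so that
    in a balanced design the interaction column is orthogonal to the main
    effects and its coefficient is half the difference-of-differences.
    """

    matrix: np.ndarray            # n x p, first columns [1, D, A, D*A]
    names: list
    subject_ids: list

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError(f"rank-deficient design; columns: {self.names}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def term_column(self, term: str) -> int:
        return {"diagnosis": 1, "age": 2, "interaction": 3}[term]


def design_from_table(df: pd.DataFrame, covariates: bool = True) -> DesignInfo:
    """Build the [1, D, A, D*A, sex, site...] design from a subjects table."""
    d = np.where(df["diagnosis"].to_numpy() == "ADHD", 1.0, -1.0)
    a = np.where(df["age_group"].to_numpy() == "adolescent", 1.0, -1.0)
    cols = [np.ones(len(df)), d, a, d * a]
    names = ["intercept", "diagnosis", "age", "interaction"]
    if covariates:
        # covariates without variation carry no information and would
        # only make the design singular (possible in tiny cohorts)
        if df["sex"].nunique() > 1:
            cols.append(np.where(df["sex"].to_numpy() == "M", 1.0, -1.0))
            names.append("sex")
        sites = sorted(df["site"].unique())
        for s in sites[1:]:
            cols.append((df["site"].to_numpy() == s).astype(float))
            names.append(f"site[{s}]")
    return DesignInfo(
        matrix=np.column_stack(cols),
        names=names,
        subject_ids=list(df["id"]),
    )


@dataclass
class StatMap:
    """Per-voxel statistic map with degrees of freedom."""

    statistic: np.ndarray
    kind: str                    # "t" | "F"
    df: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("t", "F"):
            raise ValueError(f"unknown statistic kind {self.kind!r}")

    def z_equivalent(self) -> np.ndarray:
        """Equivalent normal quantile: one-tailed for F, two-tailed |z| for t."""
        s = self.statistic
        with np.errstate(invalid="ignore"):
            if self.kind == "F":
                p = spstats.f.sf(s, *self.df)
            else:
                p = 2 * spstats.t.sf(np.abs(s), self.df[0])
                p = p / 2
        z = spstats.norm.isf(np.clip(p, 1e-300, 1.0))
        return z


@dataclass
class ClusterResult:
    clusters: list                # dicts: voxels, size, peak_stat, corrected_p
    threshold_used: float
    n_permutations: int
    seed: int
    term: str = ""
    connectivity: int = 26
    correction: str = "Freedman-Lane max-cluster-size permutation"

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c["corrected_p"] < alpha]


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str                  # "exact" | "normal-approx"

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")


def one_sample_t(maps: np.ndarray) -> StatMap:
    """Voxelwise one-sample t against zero; maps is subjects x voxels."""
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    t = np.full(maps.shape[1], np.nan)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} zero-variance voxels set to missing", RuntimeWarning
        )
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    return StatMap(statistic=t, kind="t", df=(n - 1,))


def _ols_term_t(x: np.ndarray, y: np.ndarray, pinv: np.ndarray,
                xtx_inv_diag: np.ndarray) -> np.ndarray:
    """t statistics of every coefficient; y is n x V. Returns p x V.

    Voxels with (numerically) zero residual variance get t = +/-inf for
    coefficients that are nonzero and t = 0 for coefficients that are
    zero up to float cancellation.
    """
    beta = pinv @ y
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    scale = (y**2).mean(axis=0)
    degenerate = sigma2 <= 1e-20 * np.maximum(scale, 1e-300)
    se = np.sqrt(np.maximum(sigma2[None, :] * xtx_inv_diag[:, None], 1e-300))
    t = beta / se
    if degenerate.any():
        b = beta[:, degenerate]
        tol = 1e-8 * np.maximum(np.abs(b).max(axis=0, keepdims=True), 1e-300)
        t[:, degenerate] = np.where(np.abs(b) > tol, np.sign(b) * np.inf, 0.0)
    return t


def glm_interaction(maps: np.ndarray, design: DesignInfo) -> dict:
    """Voxelwise OLS of gradient maps on [1, D, A, D*A, covariates].

    Returns the interaction F map (squared t of the D*A coefficient,
    df (1, n - p)) and the two main-effect t maps from the same model.
    """
    y = np.asarray(maps, dtype=float)
    x = design.matrix
    n, p = x.shape
    if n <= p:
        raise ValueError("more design columns than subjects")
    pinv = np.linalg.pinv(x)
    xtx_inv_diag = (pinv**2).sum(axis=1)
    t_all = _ols_term_t(x, y, pinv, xtx_inv_diag)
    dof = n - p
    return {
        "F_interaction": StatMap(
            statistic=t_all[design.term_column("interaction")] ** 2,
            kind="F", df=(1, dof),
        ),
        "t_main_diagnosis": StatMap(
            statistic=t_all[design.term_column("diagnosis")], kind="t", df=(dof,)
        ),
        "t_main_age": StatMap(
            statistic=t_all[design.term_column("age")], kind="t", df=(dof,)
        ),
    }


def _clusters_from_z(z: np.ndarray, threshold: float, geometry: MaskGeometry,
                     stat: np.ndarray):
    """Label supra-threshold voxels in 3-D and return cluster index sets."""
    supra = np.zeros(geometry.n_voxels, dtype=bool)
    finite = np.isfinite(z)
    supra[finite] = z[finite] > threshold
    vol = geometry.volume_from_vector(supra.astype(float), background=0.0)
    labeled, n_lab = ndimage.label(vol > 0.5, structure=CONN_26)
    lab_vec = geometry.vector_from_volume(labeled.astype(float)).astype(int)
    clusters = []
    for lab in range(1, n_lab + 1):
        vox = np.flatnonzero(lab_vec == lab)
        clusters.append(
            {
                "voxels": vox,
                "size": int(vox.size),
                "peak_stat": float(np.nanmax(stat[vox])),
            }
        )
    return clusters


def permutation_cluster(maps: np.ndarray, design: DesignInfo, term: str,
                        geometry: MaskGeometry, cluster_z: float | None = None,
                        n_perm: int = 1000, seed: int = 0) -> ClusterResult:
    """Cluster-corrected inference for one model term.

    Freedman-Lane scheme: the maps are residualized on the reduced model
    (all columns but the tested term), residual rows are permuted and the
    reduced-model fit added back, the full model is refit, and the
    maximum supra-threshold cluster size is recorded.  Corrected p of an
    observed cluster of size s is (1 + #{null max >= s}) / (1 + n_perm).
    """
    if term not in TERMS:
        raise ValueError(f"unknown term {term!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(maps, dtype=float)
    x = design.matrix
    col = design.term_column(term)
    if cluster_z is None:
        cluster_z = 2.3 if term == "interaction" else 2.5

    pinv = np.linalg.pinv(x)
    xtx_inv_diag = (pinv**2).sum(axis=1)
    kind = "F" if term == "interaction" else "t"
    dof = x.shape[0] - x.shape[1]

    def stat_and_z(yy: np.ndarray):
        t_all = _ols_term_t(x, yy, pinv, xtx_inv_diag)
        t_term = t_all[col]
        if kind == "F":
            sm = StatMap(statistic=t_term**2, kind="F", df=(1, dof))
        else:
            sm = StatMap(statistic=t_term, kind="t", df=(dof,))
        return sm.statistic, sm.z_equivalent()

    obs_stat, obs_z = stat_and_z(y)
    clusters = _clusters_from_z(obs_z, cluster_z, geometry, obs_stat)

    # reduced model for the Freedman-Lane null
    x0 = np.delete(x, col, axis=1)
    pinv0 = np.linalg.pinv(x0)
    fitted0 = x0 @ (pinv0 @ y)
    resid0 = y - fitted0

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    n = y.shape[0]
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted0 + resid0[perm]
        _, z_star = stat_and_z(y_star)
        cl = _clusters_from_z(z_star, cluster_z, geometry, z_star)
        null_max[b] = max((c["size"] for c in cl), default=0)

    for c in clusters:
        c["corrected_p"] = float(
            (1 + np.sum(null_max >= c["size"])) / (1 + n_perm)
        )

    return ClusterResult(
        clusters=clusters,
        threshold_used=float(cluster_z),
        n_permutations=n_perm,
        seed=seed,
        term=term,
    )


def mann_whitney(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs with x > y (ties count one half).  The p-value is
    exact (full enumeration of rank assignments) when n1 + n2 <= 20 and
    there are no ties, otherwise a normal approximation with tie and
    continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    ranks = spstats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if n1 + n2 <= 20 and not has_ties:
        method = "exact"
        p = float(
            spstats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    else:
        method = "normal-approx"
        p = float(
            spstats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
    return RankTestResult(u_statistic=float(u), p_value=p, n1=n1, n2=n2, method=method)


POSTHOC_PAIRS = (
    ("ADHD-adolescent", "HC-adolescent"),
    ("ADHD-child", "HC-child"),
    ("HC-adolescent", "HC-child"),
    ("ADHD-adolescent", "ADHD-child"),
)


def posthoc_cluster_comparisons(maps: np.ndarray, clusters: ClusterResult,
                                df: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster pairwise rank tests on subject-level cluster means.

    For every cluster, each subject's gradient is averaged over the
    cluster voxels and the four diagnosis/age pairwise comparisons are
    tested with Mann-Whitney U.
    """
    y = np.asarray(maps, dtype=float)
    cell = (df["diagnosis"] + "-" + df["age_group"]).to_numpy()
    rows = []
    for ci, c in enumerate(clusters.clusters):
        if c["size"] == 0:
            raise ValueError("empty cluster")
        means = y[:, c["voxels"]].mean(axis=1)
        for g1, g2 in POSTHOC_PAIRS:
            res = mann_whitney(means[cell == g1], means[cell == g2])
            rows.append(
                {
                    "cluster": ci,
                    "cluster_size": c["size"],
                    "corrected_p_cluster": c.get("corrected_p", np.nan),
                    "group1": g1,
                    "group2": g2,
                    "u": res.u_statistic,
                    "p": res.p_value,
                    "n1": res.n1,
                    "n2": res.n2,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
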