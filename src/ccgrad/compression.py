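"""Distributional analysis of gradient maps.

Histogram densities of pooled voxel-level gradient values per network,
distribution-shift rank tests, the full-range (FR) compression statistic
with covariate-residualized group comparisons, per-site symptom
rescaling and clinical Pearson correlations.

Pooling convention: for histograms and shift tests, gradient values of
all voxels carrying a network label are concatenated across all subjects
of a group (subject-major order), giving voxel-observation pools of size
n_subjects x n_network_voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .stats import RankTestResult, mann_whitney


@dataclass
class HistogramDensity:
    """Area-1 histogram of a pooled gradient-value sample."""

    bin_edges: np.ndarray
    density: np.ndarray
    group: str
    network: str
    pooled_n: int

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if (widths <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        area = float((self.density * widths).sum())
        if abs(area - 1.0) > 1e-9:
            raise ValueError(f"histogram area {area} != 1")


@dataclass
class FRRecord:
    subject_id: str
    structure: str               # "cortex" | "cerebellum"
    fr: float

    def __post_init__(self) -> None:
        if self.fr < 0:
            raise ValueError("full range must be nonnegative")


@dataclass
class ClinicalResult:
    region: str
    score: str
    pearson_r: float
    p_value: float
    p_adjusted: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.n < 3:
            raise ValueError("need n >= 3")


def pooled_network_values(maps: np.ndarray, network_label: np.ndarray,
                          network: str | int | None = None) -> np.ndarray:
    """Concatenate gradient values over a network's voxels across subjects.

    ``maps`` is subjects x voxels; ``network`` selects a label value
    (or None / "ALL" for the whole mask).  Subject-major order.
    """
    y = np.asarray(maps, dtype=float)
    if network is None or network == "ALL":
        sel = np.ones(y.shape[1], dtype=bool)
    else:
        sel = np.asarray(network_label) == network
        if not sel.any():
            raise ValueError(f"no voxels labeled {network!r}")
    return y[:, sel].ravel()


def histogram_density(pool: np.ndarray, n_bins: int = 100,
                      value_range: tuple | None = None,
                      group: str = "", network: str = "") -> HistogramDensity:
    """Area-1 histogram; the range should be shared across compared groups."""
    pool = np.asarray(pool, dtype=float)
    if pool.size < n_bins:
        raise ValueError("pool smaller than the number of bins")
    if value_range is None:
        value_range = (float(pool.min()), float(pool.max()))
    if value_range[1] <= value_range[0]:
        raise ValueError("zero-width histogram range")
    density, edges = np.histogram(pool, bins=n_bins, range=value_range, density=True)
    return HistogramDensity(
        bin_edges=edges, density=density, group=group, network=network,
        pooled_n=int(pool.size),
    )


def shift_test(pool_a: np.ndarray, pool_b: np.ndarray) -> RankTestResult:
    """Mann-Whitney U on two pooled voxel-value samples.

    Pools are typically large (subjects x voxels), so the normal
    approximation applies automatically.
    """
    return mann_whitney(pool_a, pool_b)


def full_range(values: np.ndarray) -> float:
    """Span of a gradient map: largest minus smallest value."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two in-mask voxels")
    return float(v.max() - v.min())


def residualize(values: np.ndarray, df: pd.DataFrame) -> np.ndarray:
    """OLS residuals of a subject-level quantity on [1, sex, site dummies]."""
    y = np.asarray(values, dtype=float)
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if df["sex"].nunique() > 1:
        cols.append(np.where(df["sex"].to_numpy() == "M", 1.0, -1.0))
        names.append("sex")
    for s in sorted(df["site"].unique())[1:]:
        cols.append((df["site"].to_numpy() == s).astype(float))
        names.append(f"site[{s}]")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient covariate design: {names}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def compare_fr(fr_values: np.ndarray, df: pd.DataFrame,
               adjust_covariates: bool = True) -> dict:
    """ADHD vs HC comparison of the full range, in the three age strata.

    FR is residualized on sex and site (once, over all subjects), then
    Mann-Whitney U tests are run within children, within adolescents,
    and pooled.  Returns {"children": ..., "adolescents": ..., "all": ...}.
    """
    fr = np.asarray(fr_values, dtype=float)
    if adjust_covariates:
        try:
            vals = residualize(fr, df)
        except ValueError as exc:
            warnings.warn(f"FR covariate adjustment skipped: {exc}", RuntimeWarning)
            vals = fr
    else:
        vals = fr
    diag = df["diagnosis"].to_numpy()
    ageg = df["age_group"].to_numpy()
    out = {}
    for name, sel in (
        ("children", ageg == "child"),
        ("adolescents", ageg == "adolescent"),
        ("all", np.ones(len(df), dtype=bool)),
    ):
        a = vals[sel & (diag == "ADHD")]
        h = vals[sel & (diag == "HC")]
        if a.size < 2 or h.size < 2:
            raise ValueError(f"stratum {name}: need >= 2 subjects per group")
        out[name] = mann_whitney(a, h)
    return out


def rescale_symptoms(df: pd.DataFrame,
                     score_columns=("inattention", "hyperactivity_impulsivity")
                     ) -> pd.DataFrame:
    """Rescale each symptom subscale to [0, 1] within site.

    Every score is divided by its within-site maximum, so each site's
    maximum maps to exactly 1.0 and scores are comparable across rating
    instruments that differ between sites.
    """
    out = df.copy()
    for col in score_columns:
        for site, sub in df.groupby("site"):
            mx = sub[col].max()
            if not np.isfinite(mx) or mx <= 0:
                raise ValueError(f"nonpositive maximum for {col!r} at site {site!r}")
            out.loc[df["site"] == site, col] = df.loc[df["site"] == site, col] / mx
    return out


def clinical_correlation(region_means: dict, scores: pd.DataFrame,
                         score_columns=("inattention", "hyperactivity_impulsivity")
                         ) -> list:
    """Pearson correlation of per-region gradient means with symptom scores.

    ``region_means`` maps region id -> per-subject vector aligned with
    ``scores`` rows.  Subjects with missing scores are dropped per score.
    Returns a list of :class:`ClinicalResult` with both uncorrected and
    Benjamini-Hochberg adjusted p-values.
    """
    raw = []
    for region, means in region_means.items():
        means = np.asarray(means, dtype=float)
        for col in score_columns:
            s = scores[col].to_numpy(dtype=float)
            ok = np.isfinite(s) & np.isfinite(means)
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 subjects for {region}/{col}")
            if np.std(s[ok]) == 0 or np.std(means[ok]) == 0:
                raise ValueError(f"zero variance for {region}/{col}")
            r, p = spstats.pearsonr(means[ok], s[ok])
            raw.append((region, col, float(r), float(p), int(ok.sum())))
    _, p_adj, *_ = multipletests([x[3] for x in raw], method="fdr_bh")
    return [
        ClinicalResult(region=reg, score=col, pearson_r=r, p_value=p,
                       p_adjusted=float(pa), n=n)
        for (reg, col, r, p, n), pa in zip(raw, p_adj)
    ]
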