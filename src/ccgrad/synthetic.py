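"""Synthetic cohort generator with a planted cerebro-cerebellar gradient.

The generator emulates the statistical structure a gradient-compression
study assumes, so that every downstream stage of the pipeline has a known
ground truth:

* a latent 1-D position ``u`` in [-1, 1] per cortical voxel and ``v`` per
  cerebellar voxel, organised by a seven-network parcellation whose
  archetype positions run from the visual network (VN, -0.9) to the
  default-mode network (DMN, +0.9);
* cross-structure connectivity that decays with |u_i - v_j|, so a
  diffusion-map embedding of the connectivity profiles recovers ``u``;
* a 2x2 diagnosis-by-age design: healthy adolescents' DMN voxels shift up
  and VN voxels shift down relative to children (a developmental
  divergence of the gradient poles), while in patients all positions are
  multiplied by a compression factor ``kappa`` and the developmental
  shift is absent in adolescents;
* two acquisition sites with a multiplicative connectivity-scale
  difference, and a male-skewed sex assignment, so covariate control is
  non-trivial;
* symptom scores negatively coupled to the planted position of a
  designated DMN sub-region, with a higher intercept in patients.

Two generation modes are provided.  ``"timeseries"`` simulates voxel
time series from shared latent AR(1) sources, exercising the temporal
preprocessing and correlation stages; ``"connectivity"`` plants the
Fisher-Z connectivity kernel directly and is used for statistical-power
experiments where many replicate cohorts are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .masks import MaskGeometry, sheet_mask

CELLS = ("HC-child", "HC-adolescent", "ADHD-child", "ADHD-adolescent")

#: Canonical seven-network labels in archetype-position order.
NETWORK_NAMES = ("VN", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")

DEFAULT_NETWORK_CENTERS = {
    "VN": -0.9,
    "SMN": -0.6,
    "DAN": -0.3,
    "VAN": -0.1,
    "LIM": 0.2,
    "FPN": 0.5,
    "DMN": 0.9,
}


#: AR(1) latent-source model used by the timeseries mode.
N_SOURCES = 12
AR_COEF = 0.3
LOADING_BANDWIDTH = 0.35

#: Connectivity-kernel parameters shared by both modes.
KERNEL_Z0 = 1.0
KERNEL_SIGMA = 0.5

#: Multiplicative connectivity-scale difference of the second site.
SITE_SCALE = {"siteA": 1.0, "siteB": 1.1}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults encode the planted-effect condition used throughout the test
    suite: compression factor ``kappa = 0.7`` and developmental pole
    shifts of 0.15 position units; set ``kappa = 1`` and the deltas to 0
    for a null cohort.
    """

    n_per_cell: int = 20
    v_ctx: int = 300
    v_cb: int = 120
    t_points: int = 150
    tr: float = 2.0
    network_centers: dict = field(
        default_factory=lambda: dict(DEFAULT_NETWORK_CENTERS)
    )
    delta_dmn: float = 0.15
    delta_vn: float = 0.15
    kappa: float = 0.7
    noise_sigma: float = 0.1
    symptom_slope: float = 1.0
    symptom_noise: float = 0.5
    symptom_intercept_hc: float = 2.0
    symptom_intercept_adhd: float = 3.5
    mode: Literal["timeseries", "connectivity"] = "timeseries"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if not (0 < self.kappa <= 1):
            raise ValueError("kappa must lie in (0, 1]")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        centers = np.array(list(self.network_centers.values()), dtype=float)
        if not (centers.min() < 0 < centers.max()):
            raise ValueError("network_centers must span negative and positive values")
        if self.mode not in ("timeseries", "connectivity"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PlantedTruth:
    """Ground-truth latent structure for one design cell."""

    cell: str
    u: np.ndarray                    # cortical positions, shape (v_ctx,)
    v: np.ndarray                    # cerebellar positions, shape (v_cb,)
    network_label: np.ndarray        # 1..7 per cortical voxel
    network_label_cb: np.ndarray     # 1..7 per cerebellar voxel
    shifted_sets: dict               # network name -> cortical voxel indices
    symptom_region: np.ndarray       # cortical voxel indices (DMN sub-region)

    def __post_init__(self) -> None:
        if len(self.u) != len(self.network_label):
            raise ValueError("u and network_label lengths differ")
        if len(self.v) != len(self.network_label_cb):
            raise ValueError("v and network_label_cb lengths differ")


@dataclass
class SubjectRecord:
    id: str
    diagnosis: str                   # "ADHD" | "HC"
    age_years: float
    age_group: str                   # "child" | "adolescent"
    sex: str                         # "M" | "F"
    site: str
    inattention: float
    hyperactivity_impulsivity: float

    def __post_init__(self) -> None:
        child = 7.0 <= self.age_years < 12.0
        adolescent = 12.0 <= self.age_years <= 18.0
        if self.age_group == "child" and not child:
            raise ValueError(f"{self.id}: age {self.age_years} outside child band")
        if self.age_group == "adolescent" and not adolescent:
            raise ValueError(f"{self.id}: age {self.age_years} outside adolescent band")

    @property
    def cell(self) -> str:
        return f"{self.diagnosis}-{self.age_group}"


@dataclass
class CohortTable:
    """Subject records plus per-subject data handles and the planted truth."""

    records: list
    data: dict                       # subject id -> data handle
    truth: dict                      # cell -> PlantedTruth
    mask_ctx: MaskGeometry
    mask_cb: MaskGeometry
    config: CohortConfig

    def __post_init__(self) -> None:
        cells = {r.cell for r in self.records}
        if set(CELLS) - cells:
            raise ValueError(f"empty design cells: {sorted(set(CELLS) - cells)}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "diagnosis": r.diagnosis,
                    "age": r.age_years,
                    "age_group": r.age_group,
                    "sex": r.sex,
                    "site": r.site,
                    "inattention": r.inattention,
                    "hyperactivity_impulsivity": r.hyperactivity_impulsivity,
                }
                for r in self.records
            ]
        )


def assign_network_labels(n_voxels: int, centers: dict) -> np.ndarray:
    """Partition canonical voxel order into contiguous network blocks.

    Networks are laid out in ascending archetype-position order, so the
    planted gradient varies smoothly across the synthetic sheet and each
    network occupies a spatially contiguous patch.
    """
    names = sorted(centers, key=centers.get)
    sizes = np.full(len(names), n_voxels // len(names), dtype=int)
    sizes[: n_voxels % len(names)] += 1
    labels = np.empty(n_voxels, dtype=int)
    start = 0
    for name, size in zip(names, sizes):
        labels[start : start + size] = NETWORK_NAMES.index(name) + 1
        start += size
    return labels


def network_indices(labels: np.ndarray, name: str) -> np.ndarray:
    return np.flatnonzero(labels == NETWORK_NAMES.index(name) + 1)


def _network_segments(centers: dict) -> dict:
    """Contiguous position segments per network, tiling [-1, 1].

    Segment boundaries sit at the midpoints between consecutive network
    archetype positions (outer edges at +/-1), so the latent hierarchy is
    continuous across the axis the way real macroscale gradients are:
    voxel positions cover [-1, 1] without gaps, while each network's mean
    position tracks its archetype and the archetype ordering is kept.
    """
    names = sorted(centers, key=centers.get)
    vals = np.array([centers[n] for n in names], dtype=float)
    mids = (vals[1:] + vals[:-1]) / 2
    edges = np.concatenate([[-1.0], mids, [1.0]])
    return {n: (edges[i], edges[i + 1]) for i, n in enumerate(names)}


def plant_positions(config: CohortConfig, cell: str) -> PlantedTruth:
    """Draw latent voxel positions for one design cell.

    The base positions are drawn once from ``config.seed`` (identical
    across cells): each voxel's position is uniform within its network's
    segment of the axis (see :func:`_network_segments`), so the base
    distribution is continuous on [-1, 1].  Cell adjustments are then
    deterministic:

    * HC-child: base positions.
    * HC-adolescent: DMN voxels shifted outward by ``+delta_dmn`` on
      average and VN voxels by ``-delta_vn`` on average (poles diverge
      with development).  The shift tapers linearly from zero at the
      network's inner segment edge to twice the delta at the pole, so
      development stretches the pole without tearing the position
      continuum; the mean shift over the network equals the delta up to
      Monte-Carlo error of the base draw.
    * ADHD cells: all positions multiplied by ``kappa``; the
      developmental shift is omitted in ADHD-adolescents.

    Shifted DMN/VN voxels may exceed the nominal [-1, 1] range; the
    connectivity kernel is defined for any real position.
    """
    if cell not in CELLS:
        raise ValueError(f"unknown design cell {cell!r}; expected one of {CELLS}")
    rng = np.random.default_rng(config.seed)
    centers = config.network_centers
    lab_ctx = assign_network_labels(config.v_ctx, centers)
    lab_cb = assign_network_labels(config.v_cb, centers)
    segments = _network_segments(centers)

    def draw(labels: np.ndarray) -> np.ndarray:
        pos = np.empty(labels.size)
        raw = rng.random(labels.size)
        for name in NETWORK_NAMES:
            lo, hi = segments[name]
            sel = labels == NETWORK_NAMES.index(name) + 1
            pos[sel] = lo + (hi - lo) * raw[sel]
        return pos

    u = draw(lab_ctx)
    v = draw(lab_cb)

    dmn_ctx = network_indices(lab_ctx, "DMN")
    vn_ctx = network_indices(lab_ctx, "VN")
    dmn_cb = network_indices(lab_cb, "DMN")
    vn_cb = network_indices(lab_cb, "VN")

    diagnosis, age_group = cell.split("-")
    if diagnosis == "ADHD":
        u = config.kappa * u
        v = config.kappa * v
    if cell == "HC-adolescent":
        u = u.copy()
        v = v.copy()
        dmn_lo, dmn_hi = segments["DMN"]
        vn_lo, vn_hi = segments["VN"]

        def stretch_up(pos, idx, delta, lo, hi):
            frac = (pos[idx] - lo) / (hi - lo)
            pos[idx] = pos[idx] + 2 * delta * frac

        def stretch_down(pos, idx, delta, lo, hi):
            frac = (hi - pos[idx]) / (hi - lo)
            pos[idx] = pos[idx] - 2 * delta * frac

        stretch_up(u, dmn_ctx, config.delta_dmn, dmn_lo, dmn_hi)
        stretch_down(u, vn_ctx, config.delta_vn, vn_lo, vn_hi)
        stretch_up(v, dmn_cb, config.delta_dmn, dmn_lo, dmn_hi)
        stretch_down(v, vn_cb, config.delta_vn, vn_lo, vn_hi)

    # symptom region: a compact DMN sub-region (IPL-like), middle 12 voxels
    mid = len(dmn_ctx) // 2
    region = dmn_ctx[max(0, mid - 6) : mid + 6]

    return PlantedTruth(
        cell=cell,
        u=u,
        v=v,
        network_label=lab_ctx,
        network_label_cb=lab_cb,
        shifted_sets={"DMN": dmn_ctx, "VN": vn_ctx, "DMN_cb": dmn_cb, "VN_cb": vn_cb},
        symptom_region=region,
    )


def _ar1_sources(n_sources: int, t_points: int, rng: np.random.Generator) -> np.ndarray:
    """Latent AR(1) sources, lag-1 coefficient 0.3, unit innovation variance."""
    burn = 50
    eps = rng.standard_normal((burn + t_points, n_sources))
    src = np.empty_like(eps)
    src[0] = eps[0] / np.sqrt(1 - AR_COEF**2)
    for t in range(1, burn + t_points):
        src[t] = AR_COEF * src[t - 1] + eps[t]
    return src[burn:]


def _loadings(positions: np.ndarray) -> np.ndarray:
    """Row-normalized Gaussian-kernel loadings onto the latent sources."""
    centers = np.linspace(-1, 1, N_SOURCES)
    w = np.exp(-((positions[:, None] - centers[None, :]) ** 2) / (2 * LOADING_BANDWIDTH**2))
    return w / w.sum(axis=1, keepdims=True)


def simulate_timeseries(
    truth: PlantedTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    site_scale: float = 1.0,
):
    """Simulate a (cortex, cerebellum) pair of voxel time series.

    Both structures load on the same latent AR(1) sources through
    position-dependent Gaussian-kernel loadings, so the cortex-cerebellum
    cross-correlation decays with |u_i - v_j|.  Returns two arrays of
    shape (T, V); wrap in :class:`ccgrad.preprocess.VoxelTimeSeries` for
    the cleaning stages.
    """
    if config.t_points < 30:
        raise ValueError("t_points must be >= 30 for stable correlation estimates")
    src = _ar1_sources(N_SOURCES, config.t_points, rng)
    w_ctx = _loadings(truth.u)
    w_cb = _loadings(truth.v)
    ts_ctx = site_scale * (src @ w_ctx.T)
    ts_cb = site_scale * (src @ w_cb.T)
    ts_ctx = ts_ctx + config.noise_sigma * rng.standard_normal(ts_ctx.shape)
    ts_cb = ts_cb + config.noise_sigma * rng.standard_normal(ts_cb.shape)
    return ts_ctx, ts_cb


def simulate_connectivity(
    truth: PlantedTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    site_scale: float = 1.0,
    z0: float = KERNEL_Z0,
    sigma: float = KERNEL_SIGMA,
) -> np.ndarray:
    """Plant a cortex x cerebellum correlation matrix directly.

    Fisher-Z connectivity follows a Gaussian kernel of the latent
    position difference, ``z_ij = z0 exp(-(u_i - v_j)^2 / (2 sigma^2))``
    plus white noise of SD ``config.noise_sigma``; correlations are
    ``tanh(z)``.  Returns the (v_ctx, v_cb) r-scale matrix.
    """
    dist2 = (truth.u[:, None] - truth.v[None, :]) ** 2
    z = site_scale * z0 * np.exp(-dist2 / (2 * sigma**2))
    z = z + config.noise_sigma * rng.standard_normal(z.shape)
    return np.tanh(z)


def simulate_symptoms(
    truth: PlantedTruth,
    record: SubjectRecord,
    region_mean: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SubjectRecord:
    """Attach symptom scores negatively coupled to the DMN region position.

    ``score = intercept - slope * region_mean + noise`` clipped at zero,
    with a higher intercept in patients so the groups separate the way
    clinical rating scales do.  ``region_mean`` is the mean planted
    position over the symptom region for the subject's design cell.
    """
    if len(truth.symptom_region) == 0:
        raise ValueError("symptom_region is empty")
    intercept = (
        config.symptom_intercept_adhd
        if record.diagnosis == "ADHD"
        else config.symptom_intercept_hc
    )
    hi = intercept - config.symptom_slope * region_mean + config.symptom_noise * rng.standard_normal()
    ia = intercept - config.symptom_slope * region_mean + config.symptom_noise * rng.standard_normal()
    return replace(
        record,
        hyperactivity_impulsivity=float(max(hi, 0.0)),
        inattention=float(max(ia, 0.0)),
    )


def build_cohort(config: CohortConfig) -> CohortTable:
    """Generate the full synthetic cohort (records, data, truth).

    Fully deterministic given ``config`` (including ``config.seed``):
    subject-level randomness is drawn from seeds spawned from the master
    seed sequence in a fixed order.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_design = np.random.default_rng(ss.spawn(1)[0])

    truths = {cell: plant_positions(config, cell) for cell in CELLS}
    mask_ctx = sheet_mask(config.v_ctx, "cortex")
    mask_cb = sheet_mask(config.v_cb, "cerebellum")

    records: list[SubjectRecord] = []
    data: dict[str, object] = {}
    n_total = 4 * config.n_per_cell
    subject_seeds = ss.spawn(n_total)
    i = 0
    for cell in CELLS:
        diagnosis, age_group = cell.split("-")
        truth = truths[cell]
        region_mean = float(truth.u[truth.symptom_region].mean())
        for _ in range(config.n_per_cell):
            rng_s = np.random.default_rng(subject_seeds[i])
            sid = f"sub-{i + 1:03d}"
            age = (
                rng_design.uniform(7.0, 12.0 - 1e-9)
                if age_group == "child"
                else rng_design.uniform(12.0, 18.0)
            )
            sex = "M" if rng_design.random() < 0.65 else "F"
            site = "siteA" if rng_design.random() < 0.6 else "siteB"
            rec = SubjectRecord(
                id=sid,
                diagnosis=diagnosis,
                age_years=float(age),
                age_group=age_group,
                sex=sex,
                site=site,
                inattention=np.nan,
                hyperactivity_impulsivity=np.nan,
            )
            rec = simulate_symptoms(truth, rec, region_mean, config, rng_s)
            scale = SITE_SCALE[site]
            if config.mode == "timeseries":
                data[sid] = simulate_timeseries(truth, config, rng_s, site_scale=scale)
            else:
                data[sid] = simulate_connectivity(truth, config, rng_s, site_scale=scale)
            records.append(rec)
            i += 1

    return CohortTable(
        records=records,
        data=data,
        truth=truths,
        mask_ctx=mask_ctx,
        mask_cb=mask_cb,
        config=config,
    )
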