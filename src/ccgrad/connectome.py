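"""Cross-structure connectivity: Pearson correlation, Fisher Z, row-wise
sparsification of connectivity profiles.

The object of study is the rectangular cortex x cerebellum matrix (and
its transpose for the cerebellar-side analysis); each row is one source
voxel's connectivity profile over the target structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse as spsparse


@dataclass
class ConnectivityMatrix:
    """Source x target voxel connectivity, on the r or Fisher-Z scale."""

    values: np.ndarray
    source_mask_id: str = "source"
    target_mask_id: str = "target"
    scale: str = "r"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("connectivity values must be 2-D")
        if self.scale not in ("r", "z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "r" and np.abs(self.values).max(initial=0) > 1 + 1e-12:
            raise ValueError("r-scale values must lie in [-1, 1]")


@dataclass
class SparseProfileMatrix:
    """Row-sparse nonnegative profile matrix (stored dense, zeros explicit)."""

    values: np.ndarray
    density: float
    source_mask_id: str = "source"
    target_mask_id: str = "target"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("sparse profile values must be nonnegative")

    def to_coo(self) -> spsparse.coo_matrix:
        return spsparse.coo_matrix(self.values)


def cross_correlation(src_data: np.ndarray, tgt_data: np.ndarray,
                      source_mask_id: str = "source",
                      target_mask_id: str = "target") -> ConnectivityMatrix:
    """Pearson correlation of every source voxel with every target voxel.

    Both inputs are T x V matrices sharing the time axis.
    """
    src = np.asarray(src_data, dtype=float)
    tgt = np.asarray(tgt_data, dtype=float)
    if src.shape[0] != tgt.shape[0]:
        raise ValueError("source and target must share the time axis")
    sc = src - src.mean(axis=0)
    tc = tgt - tgt.mean(axis=0)
    sn = np.linalg.norm(sc, axis=0)
    tn = np.linalg.norm(tc, axis=0)
    # zero variance up to float cancellation of the mean subtraction
    s_tol = 1e-10 * (1 + np.abs(src).max(axis=0))
    t_tol = 1e-10 * (1 + np.abs(tgt).max(axis=0))
    bad_s = np.flatnonzero(sn <= s_tol)
    bad_t = np.flatnonzero(tn <= t_tol)
    if bad_s.size or bad_t.size:
        raise ValueError(
            f"zero-variance voxels: source {bad_s.tolist()}, target {bad_t.tolist()}"
        )
    r = (sc / sn).T @ (tc / tn)
    np.clip(r, -1.0, 1.0, out=r)
    return ConnectivityMatrix(
        values=r, source_mask_id=source_mask_id, target_mask_id=target_mask_id,
        scale="r",
    )


def fisher_z(m: ConnectivityMatrix, clamp: float = 1e-7) -> ConnectivityMatrix:
    """Fisher Z transform, atanh(r), with |r| clamped to 1 - ``clamp``."""
    if m.scale != "r":
        raise ValueError("input is already on the Fisher-Z scale")
    r = np.clip(m.values, -(1 - clamp), 1 - clamp)
    return ConnectivityMatrix(
        values=np.arctanh(r),
        source_mask_id=m.source_mask_id,
        target_mask_id=m.target_mask_id,
        scale="z",
    )


def sparsify_rows(m: ConnectivityMatrix, density: float = 0.10) -> SparseProfileMatrix:
    """Keep the top ``ceil(density * n_cols)`` entries of each row.

    Ranking is on signed values (on the Z scale this is order-equivalent
    to ranking r); ties at the cutoff are broken deterministically in
    favour of the lower column index.  Surviving negative values are
    clamped to zero so the downstream cosine affinity is nonnegative and
    the diffusion operator's Markov normalization is well defined.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    if m.scale != "z":
        raise ValueError("sparsify_rows expects a Fisher-Z matrix")
    vals = m.values
    n_rows, n_cols = vals.shape
    keep = int(np.ceil(density * n_cols))
    out = np.zeros_like(vals)
    # stable argsort of -row -> descending order, lower index first on ties
    order = np.argsort(-vals, axis=1, kind="stable")[:, :keep]
    rows = np.repeat(np.arange(n_rows), keep)
    cols = order.ravel()
    out[rows, cols] = vals[rows, cols]
    np.maximum(out, 0.0, out=out)
    return SparseProfileMatrix(
        values=out, density=density,
        source_mask_id=m.source_mask_id, target_mask_id=m.target_mask_id,
    )
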