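"""Voxel mask geometry and the canonical vector <-> volume mapping.

Every stage of the pipeline works on flat per-voxel vectors; this module
pins down the single ordering convention used throughout: in-mask voxels
are enumerated in x-fastest (Fortran) linear-index order of the 3-D grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MaskGeometry:
    """A binary voxel mask on a 3-D grid with a fixed voxel ordering.

    Parameters
    ----------
    mask : ndarray of bool, shape (nx, ny, nz)
        In-mask voxels.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine (NIfTI convention).
    mask_id : str
        Identifier used to check that data and masks belong together.
    """

    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask_id: str = "mask"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.mask.shape}")
        if self.mask.sum() == 0:
            raise ValueError("mask contains no voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def flat_order(self) -> np.ndarray:
        """Flat (Fortran-order) indices of in-mask voxels, x-fastest."""
        return np.flatnonzero(self.mask.ravel(order="F"))

    def vector_from_volume(self, vol: np.ndarray) -> np.ndarray:
        """Extract in-mask values in canonical order.

        Accepts a 3-D volume (returns shape (V,)) or a 4-D volume with
        time last (returns shape (T, V)).
        """
        vol = np.asarray(vol)
        if vol.shape[:3] != self.shape:
            raise ValueError(
                f"volume grid {vol.shape[:3]} does not match mask grid {self.shape}"
            )
        idx = self.flat_order
        if vol.ndim == 3:
            return vol.ravel(order="F")[idx]
        if vol.ndim == 4:
            flat = vol.reshape(-1, vol.shape[3], order="F")
            return flat[idx].T  # (T, V)
        raise ValueError("volume must be 3-D or 4-D")

    def volume_from_vector(self, vec: np.ndarray, background: float = np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back into the 3-D grid.

        Out-of-mask voxels are set to ``background`` (NaN by default).
        """
        vec = np.asarray(vec, dtype=float)
        if vec.ndim != 1 or vec.size != self.n_voxels:
            raise ValueError(
                f"vector length {vec.size} does not match mask size {self.n_voxels}"
            )
        flat = np.full(int(np.prod(self.shape)), background, dtype=float)
        flat[self.flat_order] = vec
        return flat.reshape(self.shape, order="F")

    def same_grid(self, other: "MaskGeometry", tol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


def sheet_mask(n_voxels: int, mask_id: str, voxel_size: float = 3.0) -> MaskGeometry:
    """Build a 1-voxel-thick rectangular sheet holding ``n_voxels`` voxels.

    Used by the synthetic cohort: a (nx, ny, 1) grid filled in canonical
    x-fastest order, so consecutive canonical indices tile the sheet row
    by row and contiguous index blocks are spatially contiguous under
    26-neighbour connectivity.
    """
    nx = int(np.ceil(np.sqrt(n_voxels)))
    ny = int(np.ceil(n_voxels / nx))
    mask = np.zeros((nx, ny, 1), dtype=bool)
    flat = np.zeros(nx * ny, dtype=bool)
    flat[:n_voxels] = True
    mask[:, :, 0] = flat.reshape((nx, ny), order="F")
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return MaskGeometry(mask=mask, affine=affine, mask_id=mask_id)
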