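"""Functional-gradient estimation: cosine affinity, anisotropic
diffusion-map embedding, template construction, Procrustes alignment,
and mapping of gradients back into volume geometry.

The embedding follows the anisotropic diffusion-map construction.  From
a symmetric nonnegative affinity ``A``:

1. density normalization ``W = D^(-alpha) A D^(-alpha)`` with
   ``D = diag(A 1)``; ``alpha`` interpolates between the graph Laplacian
   (alpha = 0), Fokker-Planck diffusion (alpha = 0.5, the default) and
   the Laplace-Beltrami operator (alpha = 1);
2. Markov normalization ``P = D'^(-1) W`` with ``D' = diag(W 1)``;
3. eigendecomposition through the symmetric conjugate
   ``S = D'^(-1/2) W D'^(-1/2)``, whose eigenvalues equal those of ``P``;
   right eigenvectors of ``P`` are ``psi_m = D'^(-1/2) v_m``, normalized
   by the trivial eigenvector so that ``psi_0 = 1`` (the convention of
   the standard diffusion-mapping toolboxes), then the trivial pair
   (lambda_0 = 1, constant psi_0) is discarded;
4. diffusion-time-0 scaling: component ``m`` is
   ``psi_m * lambda_m / (1 - lambda_m)``;
5. variance explained of component ``m`` is
   ``lambda_m^2 / sum_j lambda_j^2`` over the non-trivial spectrum.

Everything is deterministic: a dense symmetric solver is used up to
n = 2000 and an iterative solver with a fixed start vector above, and
each component's sign is fixed so its largest-magnitude entry is
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.linalg import eigsh

from .connectome import SparseProfileMatrix
from .masks import MaskGeometry

DENSE_LIMIT = 2000


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative voxel similarity kernel in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        a = self.values
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("affinity must be square")
        if np.abs(a - a.T).max() > 1e-8:
            raise ValueError("affinity must be symmetric")
        if a.min() < 0:
            raise ValueError("affinity must be nonnegative")


@dataclass
class GradientSet:
    """Embedding components with their eigenvalues and variance explained.

    ``components[:, m]`` is gradient m+1 (the trivial constant
    eigenvector is excluded); gradient 1 is the principal gradient.
    """

    components: np.ndarray        # n x k
    eigenvalues: np.ndarray       # k, descending, < 1
    variance_explained: np.ndarray
    alpha: float
    aligned_to: str | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.components.shape[1] != self.eigenvalues.size:
            raise ValueError("component/eigenvalue count mismatch")

    @property
    def n_voxels(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def gradient(self, index: int = 1) -> np.ndarray:
        """Return gradient ``index`` (1-based) as a per-voxel vector."""
        if not (1 <= index <= self.k):
            raise ValueError(f"gradient index {index} out of range 1..{self.k}")
        return self.components[:, index - 1]


def cosine_affinity(sp: SparseProfileMatrix) -> AffinityMatrix:
    """Cosine similarity (1 - cosine distance) between sparse profiles."""
    x = sp.values
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"all-zero profile rows (empty profiles): {zero.tolist()}")
    xn = x / norms[:, None]
    a = xn @ xn.T
    np.clip(a, 0.0, 1.0, out=a)
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(values=a)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    for m in range(components.shape[1]):
        col = components[:, m]
        if col[np.argmax(np.abs(col))] < 0:
            components[:, m] = -col
    return components


def diffusion_embedding(a: AffinityMatrix | np.ndarray, alpha: float = 0.5,
                        k: int = 10) -> GradientSet:
    """Anisotropic diffusion-map embedding of an affinity matrix.

    Raises if the affinity is asymmetric, negative, or describes a
    disconnected graph (second eigenvalue within 1e-10 of 1).
    """
    if not isinstance(a, AffinityMatrix):
        a = AffinityMatrix(values=np.asarray(a, dtype=float))
    av = a.values
    n = av.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    d = av.sum(axis=1)
    if (d == 0).any():
        raise ValueError("disconnected affinity: zero-degree rows present")
    dn = d ** (-alpha)
    w = av * np.outer(dn, dn)
    d2 = w.sum(axis=1)
    inv_sqrt = d2 ** -0.5
    s = w * np.outer(inv_sqrt, inv_sqrt)

    if n <= DENSE_LIMIT:
        evals, evecs = eigh(s)
        order = np.argsort(evals)[::-1][: k + 1]
        lam = evals[order]
        vecs = evecs[:, order]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        evals, evecs = eigsh(s, k=k + 1, which="LA", v0=v0)
        order = np.argsort(evals)[::-1]
        lam = evals[order]
        vecs = evecs[:, order]

    if lam[1] > 1 - 1e-10:
        raise ValueError("disconnected affinity: multiplicity of eigenvalue 1")

    # psi_0 = 1 normalization: v_0 is proportional to sqrt(d'), so the
    # elementwise quotient applies D'^(-1/2) and fixes the overall scale
    psi = vecs / vecs[:, [0]]
    lam_rest = np.clip(lam[1 : k + 1], None, 1 - 1e-12)
    comps = psi[:, 1 : k + 1] * (lam_rest / (1 - lam_rest))[None, :]
    comps = _fix_signs(comps)

    if n <= DENSE_LIMIT:
        nontrivial = np.sort(evals)[::-1][1:]
    else:
        nontrivial = lam_rest
    denom = float((nontrivial**2).sum())
    ve = lam_rest**2 / denom if denom > 0 else np.zeros(k)

    return GradientSet(
        components=comps,
        eigenvalues=lam_rest,
        variance_explained=ve,
        alpha=alpha,
    )


def transition_matrix(a: AffinityMatrix | np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """The row-stochastic diffusion operator P (test/diagnostic utility)."""
    av = a.values if isinstance(a, AffinityMatrix) else np.asarray(a, dtype=float)
    d = av.sum(axis=1)
    dn = d ** (-alpha)
    w = av * np.outer(dn, dn)
    return w / w.sum(axis=1, keepdims=True)


def alpha_limit_check(a: AffinityMatrix | np.ndarray, k: int = 5,
                      tol: float = 1e-8) -> dict:
    """Verify the alpha = 0 limit against the random-walk Laplacian of A.

    At alpha = 0 the diffusion operator reduces to ``D^(-1) A``; this
    diagnostic compares the embedding's eigenvalues with an independent
    dense eigendecomposition of that operator.
    """
    av = a.values if isinstance(a, AffinityMatrix) else np.asarray(a, dtype=float)
    emb = diffusion_embedding(av, alpha=0.0, k=k)
    d = av.sum(axis=1)
    p0 = av / d[:, None]
    ref = np.sort(np.real(np.linalg.eigvals(p0)))[::-1][1 : k + 1]
    diff = float(np.abs(np.sort(emb.eigenvalues)[::-1] - ref).max())
    return {
        "max_eigenvalue_diff": diff,
        "ok": diff < tol,
        "eigenvalues_embedding": emb.eigenvalues,
        "eigenvalues_random_walk": ref,
    }


def build_template(profiles: list[SparseProfileMatrix],
                   dmn_indices: np.ndarray | None = None,
                   alpha: float = 0.5, k: int = 10) -> GradientSet:
    """Group template: embedding of the mean sparse profile matrix.

    The element-wise mean of the subjects' sparse profiles is embedded
    once; the result anchors the Procrustes alignment of every subject.
    Sign convention: gradient 1 is flipped if needed so its mean over the
    DMN-labeled voxels is positive (the transmodal pole is the positive
    end of the principal gradient).
    """
    if len(profiles) == 0:
        raise ValueError("need at least one subject")
    shapes = {p.values.shape for p in profiles}
    if len(shapes) > 1:
        raise ValueError(f"profile shape mismatch: {sorted(shapes)}")
    mean = np.mean([p.values for p in profiles], axis=0)
    sp = SparseProfileMatrix(values=mean, density=profiles[0].density)
    tpl = diffusion_embedding(cosine_affinity(sp), alpha=alpha, k=k)
    if dmn_indices is not None and len(dmn_indices) > 0:
        g1 = tpl.components[:, 0]
        if g1[np.asarray(dmn_indices)].mean() < 0:
            tpl.components[:, 0] = -g1
    tpl.aligned_to = "template"
    return tpl


def procrustes_align(g: GradientSet, template: GradientSet,
                     template_id: str = "template") -> GradientSet:
    """Orthogonally rotate/reflect a subject's components onto a template.

    Finds the orthogonal k x k matrix R minimizing ||G R - T||_F (no
    centering, no scaling) via the SVD of G^T T, and returns G R.  This
    removes arbitrary sign flips and rotations of the embedding while
    preserving the Frobenius norm exactly.
    """
    if g.components.shape != template.components.shape:
        raise ValueError("subject and template must share n and k")
    m = g.components.T @ template.components
    if np.linalg.matrix_rank(m) < m.shape[0]:
        warnings.warn(
            "rank-deficient cross-product in Procrustes alignment; "
            "using convention singular vectors",
            RuntimeWarning,
        )
    r, _ = orthogonal_procrustes(g.components, template.components)
    return replace(g, components=g.components @ r, aligned_to=template_id)


def gradient_to_volume(g: GradientSet, component_index: int,
                       mask: MaskGeometry) -> np.ndarray:
    """Map one gradient into the mask's 3-D geometry (NaN background)."""
    if g.n_voxels != mask.n_voxels:
        raise ValueError(
            f"gradient length {g.n_voxels} does not match mask size {mask.n_voxels}"
        )
    return mask.volume_from_vector(g.gradient(component_index))
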