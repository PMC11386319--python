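"""Independent brute-force oracles used to validate the pipeline.

Each oracle is written directly from the mathematical definition and
stays independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_embedding(a: np.ndarray, alpha: float = 0.5, k: int = 10):
    """Diffusion-map embedding by explicit operator construction.

    Builds the density-normalized kernel, the row-stochastic transition
    matrix P, symmetrizes P by the exact similarity transform, and runs
    a full dense symmetric eigendecomposition.  Returns (components,
    eigenvalues) with the diffusion-time-0 scaling lambda/(1-lambda).
    """
    a = np.asarray(a, dtype=float)
    d = a.sum(axis=1)
    w = a / np.outer(d**alpha, d**alpha)
    d2 = w.sum(axis=1)
    p = w / d2[:, None]
    s = np.diag(np.sqrt(d2)) @ p @ np.diag(1.0 / np.sqrt(d2))
    s = (s + s.T) / 2
    evals, evecs = np.linalg.eigh(s)
    idx = np.argsort(evals)[::-1]
    lam = evals[idx][1 : k + 1]
    psi = evecs[:, idx] / np.sqrt(d2)[:, None]
    psi = psi / psi[:, [0]]  # psi_0 = 1 normalization
    comps = psi[:, 1 : k + 1] * (lam / (1 - lam))[None, :]
    return comps, lam


def match_up_to_sign(a: np.ndarray, b: np.ndarray) -> float:
    """Max per-column distance between two component sets, ignoring sign."""
    worst = 0.0
    for m in range(a.shape[1]):
        d = min(
            np.abs(a[:, m] - b[:, m]).max(),
            np.abs(a[:, m] + b[:, m]).max(),
        )
        worst = max(worst, d)
    return worst


def balanced_anova_interaction_f(y_cells: dict) -> float:
    """Classical sums-of-squares interaction F for a balanced 2x2 design.

    ``y_cells`` maps (level_a, level_b) -> 1-D sample of equal size n.
    Returns F = SS_AB / MS_within with df (1, 4n - 4).
    """
    n = len(next(iter(y_cells.values())))
    means = {k: np.mean(v) for k, v in y_cells.items()}
    grand = np.mean([means[k] for k in y_cells])
    a_means = {a: np.mean([means[(a, b)] for b in (0, 1)]) for a in (0, 1)}
    b_means = {b: np.mean([means[(a, b)] for a in (0, 1)]) for b in (0, 1)}
    ss_ab = n * sum(
        (means[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
        for a in (0, 1)
        for b in (0, 1)
    )
    ss_within = sum(np.sum((np.asarray(v) - means[k]) ** 2) for k, v in y_cells.items())
    df_within = 4 * n - 4
    return float(ss_ab / (ss_within / df_within))


def enumerate_u_pvalue(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of rank splits.

    Assumes no ties.  Returns (U_observed, p) with the symmetric-tail
    definition p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|).
    """
    x = list(x)
    y = list(y)
    n1, n2 = len(x), len(y)
    pool = sorted(x + y)
    u_obs = sum(xi > yj for xi in x for yj in y)
    mu = n1 * n2 / 2.0
    us = []
    for comb in itertools.combinations(range(n1 + n2), n1):
        xs = [pool[i] for i in comb]
        ys = [pool[i] for i in range(n1 + n2) if i not in comb]
        us.append(sum(xi > yj for xi in xs for yj in ys))
    us = np.array(us, dtype=float)
    p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu)))
    return float(u_obs), p


def random_orthogonal(k: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish orthogonal matrix from QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((k, k)))
    return q * np.sign(np.diag(r))
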