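"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written on a different route from the
package implementation (dense linear algebra from the incidence matrix,
plain-Python triple loops, exhaustive threshold search) so the two paths
check each other.
"""

from __future__ import annotations

import math

import numpy as np


def dense_dirichlet(n: int, edges: np.ndarray, weights: np.ndarray,
                    fg_idx: np.ndarray, bg_idx: np.ndarray) -> np.ndarray:
    """Dense Dirichlet solve built from the incidence-matrix form L = A^T C A."""
    m = len(edges)
    A = np.zeros((m, n))
    for e, (i, j) in enumerate(edges):
        A[e, i] = 1.0
        A[e, j] = -1.0
    C = np.diag(weights)
    L = A.T @ C @ A

    x = np.full(n, np.nan)
    x[fg_idx] = 1.0
    x[bg_idx] = 0.0
    labeled = ~np.isnan(x)
    unlabeled = np.nonzero(~labeled)[0]
    if unlabeled.size:
        L_UU = L[np.ix_(unlabeled, unlabeled)]
        L_UM = L[np.ix_(unlabeled, np.nonzero(labeled)[0])]
        x[unlabeled] = np.linalg.solve(L_UU, -L_UM @ x[labeled])
    return x


def brute_vldtp(volume: np.ndarray, k: float = 1.0) -> np.ndarray:
    """Plain triple-loop VLDTP: 13 axes x (-1, 0, +1), normalized counts."""
    volume = np.asarray(volume, dtype=float)
    d, h, w = volume.shape
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    axes = sorted(o for o in offsets if next(c for c in o if c != 0) > 0)
    axis_of = {}
    for i, a in enumerate(axes):
        axis_of[a] = i
        axis_of[tuple(-c for c in a)] = i

    hist = np.zeros((13, 3))
    for z in range(1, d - 1):
        for y in range(1, h - 1):
            for x in range(1, w - 1):
                window = [volume[z + dz, y + dy, x + dx]
                          for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                          for dx in (-1, 0, 1)]
                mu = sum(window) / 27.0
                sigma = math.sqrt(sum((v - mu) ** 2 for v in window) / 26.0)
                for off in offsets:
                    gp = volume[z + off[0], y + off[1], x + off[2]]
                    if gp > mu + k * sigma:
                        code = 2
                    elif gp < mu - k * sigma:
                        code = 0
                    else:
                        code = 1
                    hist[axis_of[off], code] += 1
    return hist.ravel() / ((d - 2) * (h - 2) * (w - 2))


def brute_otsu(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over a 256-bin histogram."""
    values = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    best_var, best_t = -1.0, centers[0]
    for t in range(nbins - 1):  # split after bin t
        w0 = counts[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / counts[: t + 1].sum()
        mu1 = (counts[t + 1:] * centers[t + 1:]).sum() / counts[t + 1:].sum()
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[t]
    return float(best_t)
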