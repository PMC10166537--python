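"""Hyperboloid (Lorentz) model of hyperbolic space.

Points live on the upper sheet ``{x : <x,x> = -1, x0 > 0}`` of a hyperboloid
in R^(d+1), where ``<x,y> = -x0*y0 + sum_i x_i*y_i`` is the Lorentz inner
product.  Only the d spatial coordinates are stored ("tangent" coordinates);
the time-like coordinate is recomputed on projection, so every stored state
is automatically on the sheet.

Curvature enters purely through the metric: the sheet itself is fixed at
``<x,x> = -1`` and the geodesic distance is ``arcosh(-<x,y>) / sqrt(-kappa)``.
A curvature of exactly zero selects a plain Euclidean distance on the stored
coordinates (a separate code path; the hyperbolic formula degenerates as
kappa -> 0).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = [
    "lorentz_inner",
    "project_up",
    "project_down",
    "hyperbolic_distance",
    "pairwise_distances",
    "four_point_delta",
]

#: slack allowed when clamping the arcosh argument up to 1
_ACOSH_CLAMP_TOL = 1e-12


def lorentz_inner(x: np.ndarray, y: np.ndarray) -> float:
    """Lorentz inner product ``-x0*y0 + sum_{i>=1} x_i*y_i``.

    Parameters
    ----------
    x, y : array-like, shape (d+1,)
        Vectors in ambient coordinates (first entry time-like).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError(
            f"lorentz_inner needs two equal-length vectors of size >= 2, "
            f"got shapes {x.shape} and {y.shape}"
        )
    return float(-x[0] * y[0] + x[1:] @ y[1:])


def project_up(p: np.ndarray) -> np.ndarray:
    """Lift spatial coordinates onto the hyperboloid sheet.

    Returns ``(x0, p)`` with ``x0 = sqrt(1 + |p|^2)``, which satisfies the
    on-sheet condition ``<x,x> = -1`` exactly (up to rounding).  Accepts a
    single vector of length d or a matrix of row vectors (n, d).
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("project_up requires finite coordinates")
    if p.ndim == 1:
        x0 = np.sqrt(1.0 + p @ p)
        return np.concatenate(([x0], p))
    x0 = np.sqrt(1.0 + np.einsum("ij,ij->i", p, p))
    return np.column_stack([x0, p])


def project_down(x: np.ndarray) -> np.ndarray:
    """Drop the time-like coordinate; exact inverse of :func:`project_up`."""
    x = np.asarray(x, dtype=float)
    return x[1:] if x.ndim == 1 else x[:, 1:]


def _check_negative_curvature(kappa: float) -> float:
    kappa = float(kappa)
    if not kappa < 0:
        raise ValueError(
            f"hyperbolic metric requires curvature kappa < 0, got {kappa}; "
            "Euclidean mode (kappa = 0) is a separate code path"
        )
    return kappa


def hyperbolic_distance(x: np.ndarray, y: np.ndarray, kappa: float) -> float:
    """Geodesic distance ``arcosh(-<x,y>) / sqrt(-kappa)`` on the sheet.

    Both points must be on-sheet; ``-<x,y>`` is clamped to ``[1, inf)``
    before ``arcosh`` to absorb rounding of nearly-identical points.
    """
    kappa = _check_negative_curvature(kappa)
    g = -lorentz_inner(x, y)
    if g < 1.0 - _ACOSH_CLAMP_TOL * max(1.0, abs(g)):
        raise ValueError(
            f"-<x,y> = {g} < 1: points are not both on the upper sheet"
        )
    return float(np.arccosh(max(g, 1.0)) / np.sqrt(-kappa))


def pairwise_distances(X: np.ndarray, kappa: float) -> np.ndarray:
    """All pairwise distances between stored (tangent) coordinates.

    For ``kappa < 0`` each row is lifted by :func:`project_up` and the
    hyperbolic metric applied; ``kappa == 0`` uses the Euclidean norm on the
    rows directly.  Returns a symmetric (n, n) matrix with zero diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError(f"need at least 2 points in a 2-D array, got shape {X.shape}")
    if kappa == 0:
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    else:
        kappa = _check_negative_curvature(kappa)
        x0 = np.sqrt(1.0 + np.einsum("ij,ij->i", X, X))
        # Gram matrix of -<x_i, x_j> via the Lorentz interval identity
        # G = 1 + (|xs_i - xs_j|^2 - (x0_i - x0_j)^2) / 2, which avoids the
        # catastrophic cancellation of x0_i*x0_j - xs_i.xs_j between nearby
        # points far from the origin (routine at strongly negative kappa)
        diff = X[:, None, :] - X[None, :, :]
        sq = np.einsum("ijk,ijk->ij", diff, diff)
        G = 1.0 + 0.5 * (sq - (x0[:, None] - x0[None, :]) ** 2)
        np.clip(G, 1.0, None, out=G)
        D = np.arccosh(G) / np.sqrt(-kappa)
    np.fill_diagonal(D, 0.0)
    return D


def four_point_delta(D: np.ndarray) -> float:
    """Largest four-point-condition violation over all quadruples.

    For each quadruple {i,j,k,l} form the three pair sums
    ``D_ij + D_kl``, ``D_ik + D_jl``, ``D_il + D_jk``; sorted descending as
    ``S1 >= S2 >= S3``, the quadruple violates the four-point condition by
    ``(S1 - S2) / 2``.  The returned delta is the maximum violation, the
    minimal delta for which the matrix is delta-hyperbolic.  Zero iff the
    distances are additive (realisable on a tree).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError(f"expected a square matrix, got shape {D.shape}")
    if n < 4:
        raise ValueError(f"four-point condition needs n >= 4 taxa, got {n}")
    quads = np.array(list(combinations(range(n), 4)))
    i, j, k, l = quads.T
    sums = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]])
    sums.sort(axis=0)
    return float(np.max(sums[2] - sums[1]) / 2.0)
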