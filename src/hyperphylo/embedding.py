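"""Embedding a distance matrix into the hyperboloid.

Two-stage encoder in the spirit of hydra+: a strain (eigen-decomposition)
initialisation followed by stress minimisation, here driven by L-BFGS with
an analytic gradient on the stored tangent coordinates.  The strain stage
builds ``A_ij = cosh(sqrt(-kappa) D_ij)``, which for a perfectly embeddable
matrix equals the Gram matrix ``-<x_i, x_j>`` of on-sheet points: its
leading eigenvector carries the time-like coordinates and the most negative
eigenvalues carry the spatial ones.

Also provides single-taxon placement: given q reference points and target
distances, the on-sheet point at those distances satisfies the linear
system ``S H z' = -cosh(sqrt(-kappa) d*)``, solved exactly (q = d+1) or by
least squares, then re-projected onto the sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .geometry import pairwise_distances, project_up

__all__ = ["EmbeddingConfig", "HyperbolicEmbedding", "stress", "embed_hydraplus", "place_taxon"]

#: stand-in curvature when a Euclidean (kappa = 0) embedding is requested;
#: at this magnitude the hyperboloid is flat to machine precision
_NEAR_FLAT_KAPPA = -1e-10


@dataclass
class EmbeddingConfig:
    """Encoder settings: target space and optimisation budget."""

    dimension: int = 3
    curvature: float = -1.0
    max_iterations: int = 1000
    stress_tolerance: float = 1e-8

    def __post_init__(self):
        if self.dimension < 2:
            raise ValueError(f"embedding dimension must be >= 2, got {self.dimension}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.curvature > 0:
            raise ValueError(f"curvature must be <= 0, got {self.curvature}")


@dataclass
class HyperbolicEmbedding:
    """Per-taxon tangent coordinates plus the space they live in."""

    tangent: np.ndarray
    config: EmbeddingConfig
    taxon_labels: list

    def __post_init__(self):
        self.tangent = np.asarray(self.tangent, dtype=float)
        if self.tangent.shape[0] != len(self.taxon_labels):
            raise ValueError("one coordinate row per taxon label required")
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            raise ValueError("taxon labels must be unique")


def stress(X: np.ndarray, D: np.ndarray, kappa: float) -> float:
    """Embedding stress: sum over unordered pairs of (D_ij - d(x_i, x_j))^2."""
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    if D.shape != (X.shape[0], X.shape[0]):
        raise ValueError(f"distance matrix {D.shape} does not match {X.shape[0]} points")
    R = D - pairwise_distances(X, kappa)
    return float(np.sum(np.triu(R, k=1) ** 2))


def _stress_and_grad(x: np.ndarray, D: np.ndarray, kappa: float, n: int, d: int):
    """Stress and its gradient w.r.t. the flattened tangent coordinates."""
    X = x.reshape(n, d)
    sk = np.sqrt(-kappa)
    x0 = np.sqrt(1.0 + np.einsum("ij,ij->i", X, X))
    # stable Gram of -<x_i, x_j> (see geometry.pairwise_distances)
    diff = X[:, None, :] - X[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    G = 1.0 + 0.5 * (sq - (x0[:, None] - x0[None, :]) ** 2)
    np.clip(G, 1.0, None, out=G)
    dist = np.arccosh(G) / sk
    R = D - dist
    val = 0.5 * float(np.sum(R * R))  # counts each pair once
    # d dist_ij / d X_i = (x0_j * X_i / x0_i - X_j) / (sk * sqrt(G^2 - 1))
    denom = sk * np.sqrt(np.maximum(G * G - 1.0, 1e-18))
    W = -R / denom
    np.fill_diagonal(W, 0.0)
    grad = ((W * x0[None, :]).sum(axis=1) / x0)[:, None] * X - W @ X
    return val, grad.ravel()


def _strain_init(D: np.ndarray, d: int, kappa: float) -> np.ndarray:
    """Eigen-decomposition (strain) initialisation of the embedding.

    The time-like coordinate comes from the eigenvector of the largest
    eigenvalue of ``cosh(sqrt(-kappa) D)``, the d spatial coordinates from
    the eigenvectors of the d most negative eigenvalues scaled by
    ``sqrt(max(-lambda, 0))``; each point is then renormalised onto the
    sheet by dropping the time-like part and projecting up.
    """
    sk = np.sqrt(-kappa)
    A = np.cosh(np.minimum(sk * D, 700.0))
    vals, vecs = np.linalg.eigh(A)
    # spatial part: d most negative eigenvalues (ascending order -> first d)
    lam = vals[:d]
    V = vecs[:, :d]
    X = V * np.sqrt(np.maximum(-lam, 0.0))[None, :]
    # the time-like eigenvector is discarded: projecting up from the spatial
    # part alone renormalises every point exactly onto the sheet
    return X


def embed_hydraplus(D: np.ndarray, config: EmbeddingConfig, labels=None) -> HyperbolicEmbedding:
    """Embed a distance matrix into the hyperboloid (strain init + stress descent).

    Returns tangent coordinates whose pairwise hyperbolic distances
    approximate ``D`` in least squares; the refined solution never has
    higher stress than the strain initialisation.  A requested curvature of
    zero is embedded with a minuscule negative curvature (the strain
    construction needs a hyperbolic metric), which is flat in practice.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n or n < 2:
        raise ValueError(f"expected a square matrix with n >= 2, got shape {D.shape}")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    kappa = config.curvature if config.curvature < 0 else _NEAR_FLAT_KAPPA
    d = config.dimension

    X0 = _strain_init(D, d, kappa)
    res = minimize(
        _stress_and_grad,
        X0.ravel(),
        args=(D, kappa, n, d),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iterations, "ftol": config.stress_tolerance},
    )
    X = res.x.reshape(n, d)
    if stress(X, D, kappa) > stress(X0, D, kappa):
        X = X0
    if config.curvature == 0:
        # near-flat coordinates live at scale sqrt(-kappa) * D; rescale so
        # plain Euclidean distances between the rows reproduce D
        X = X / np.sqrt(-kappa)
    return HyperbolicEmbedding(X, config, list(labels))


def place_taxon(S: np.ndarray, dstar: np.ndarray, kappa: float) -> np.ndarray:
    """Place a new point at given distances from q existing on-sheet points.

    Solves ``S H z' = -cosh(sqrt(-kappa) d*)`` (each row of ``S`` an
    on-sheet point in ambient coordinates, ``H = diag(-1, 1, ..., 1)``)
    exactly when q equals the ambient dimension, otherwise in least
    squares, and re-projects the solution onto the sheet by recomputing the
    time-like coordinate from the spatial part.
    """
    S = np.asarray(S, dtype=float)
    dstar = np.asarray(dstar, dtype=float)
    if kappa >= 0:
        raise ValueError(f"placement requires kappa < 0, got {kappa}")
    q, m = S.shape
    if q < m:
        raise ValueError(f"need at least d+1 = {m} reference points, got {q}")
    if np.any(dstar < 0) or dstar.shape != (q,):
        raise ValueError("dstar must be q non-negative distances")
    H = np.eye(m)
    H[0, 0] = -1.0
    rhs = -np.cosh(np.sqrt(-kappa) * dstar)
    A = S @ H
    if q == m:
        try:
            z = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError("degenerate reference configuration") from err
    else:
        z, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return project_up(z[1:])
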