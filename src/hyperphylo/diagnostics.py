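"""Posterior summaries and analysis instruments.

Split frequencies and the average standard deviation of split frequencies
(ASDSF) compare tree traces; tree-length summaries track branch-length
calibration; the landscape scan maps the posterior surface seen by a single
moving taxon; neighbourhood sampling characterises how far isotropic
Gaussian proposals in embedding space reach in topology space (measured by
Robinson-Foulds distance).
"""

from __future__ import annotations

import json

import numpy as np

from .evolution import Alignment, PriorConfig, log_joint
from .geometry import pairwise_distances
from .trees import neighbor_joining, rf_distance, tree_length, tree_splits

__all__ = [
    "split_frequencies",
    "asdsf",
    "tree_length_summary",
    "landscape_scan",
    "neighborhood_sample",
]


def split_frequencies(trace) -> dict:
    """Fraction of retained samples containing each non-trivial split."""
    trees = trace.trees if hasattr(trace, "trees") else list(trace)
    if not trees:
        raise ValueError("empty trace")
    counts = {}
    for T in trees:
        for s in tree_splits(T):
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    return {s: c / n for s, c in counts.items()}


def asdsf(traceA, traceB, min_freq: float = 0.10) -> float:
    """Average standard deviation of split frequencies between two runs.

    Over splits whose frequency reaches ``min_freq`` in at least one run,
    averages the across-run sample standard deviation (divisor n_runs - 1)
    of the split's frequency.  Values below 0.05 conventionally indicate
    that the two runs sample the same split distribution.  Raises if no
    split qualifies rather than reporting a vacuous zero.
    """
    fa = split_frequencies(traceA)
    fb = split_frequencies(traceB)
    qualifying = {s for s, f in fa.items() if f >= min_freq}
    qualifying |= {s for s, f in fb.items() if f >= min_freq}
    if not qualifying:
        raise ValueError(f"no split reaches min_freq = {min_freq} in either trace")
    sds = []
    for s in qualifying:
        x = np.array([fa.get(s, 0.0), fb.get(s, 0.0)])
        sds.append(np.std(x, ddof=1))
    return float(np.mean(sds))


def tree_length_summary(trace) -> dict:
    """Mean, median and sample variance of total tree length over a trace."""
    trees = trace.trees if hasattr(trace, "trees") else list(trace)
    if not trees:
        raise ValueError("empty trace")
    tl = np.array([tree_length(T) for T in trees])
    var = float(np.var(tl, ddof=1)) if tl.size > 1 else 0.0
    return {"mean": float(tl.mean()), "median": float(np.median(tl)), "variance": var}


def landscape_scan(X, moving_index, grid_x, grid_y, Y: Alignment, prior=None, kappa=-1.0):
    """Posterior landscape seen by one moving taxon on a 2-D lattice.

    All taxa but ``moving_index`` stay fixed; for each lattice point
    ``(grid_x[i], grid_y[j])`` substituted as that taxon's tangent
    coordinates, the NJ tree is decoded and three grids recorded: the
    unnormalised log posterior, the RF distance to the reference tree
    (decoded at the unperturbed ``X``), and the total tree length.
    Requires a two-dimensional embedding for the moving taxon.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if not 0 <= moving_index < n:
        raise ValueError(f"moving_index {moving_index} out of range for {n} taxa")
    if d != 2:
        raise ValueError("landscape scan requires a 2-D embedding")
    if prior is None:
        prior = PriorConfig()
    labels = list(Y.labels)
    ref = neighbor_joining(pairwise_distances(X, kappa), labels)
    nx, ny = len(grid_x), len(grid_y)
    lj = np.empty((nx, ny))
    rf = np.empty((nx, ny), dtype=int)
    tl = np.empty((nx, ny))
    W = X.copy()
    for i, gx in enumerate(grid_x):
        for j, gy in enumerate(grid_y):
            W[moving_index] = (gx, gy)
            T = neighbor_joining(pairwise_distances(W, kappa), labels)
            lj[i, j] = log_joint(T, Y, prior, W)
            rf[i, j] = rf_distance(T, ref)
            tl[i, j] = tree_length(T)
    return lj, rf, tl


def neighborhood_sample(X, scales, n_draws, kappa=-1.0, rng=None) -> dict:
    """Topology distance reached by isotropic Gaussian moves, per scale.

    For each proposal scale s, draws ``n_draws`` perturbations
    ``X + s * N(0, I)``, decodes the NJ tree and records its RF distance to
    the tree decoded at ``X``.  Returns {scale: array of RF distances}.
    """
    X = np.asarray(X, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    labels = [f"t{i}" for i in range(X.shape[0])]
    ref = neighbor_joining(pairwise_distances(X, kappa), labels)
    out = {}
    for s in scales:
        if s < 0:
            raise ValueError("scales must be >= 0")
        dists = np.empty(n_draws, dtype=int)
        for k in range(n_draws):
            W = X + s * rng.standard_normal(X.shape)
            T = neighbor_joining(pairwise_distances(W, kappa), labels)
            dists[k] = rf_distance(T, ref)
        out[float(s)] = dists
    return out


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)


def write_grid_tsv(grid, grid_x, grid_y, path) -> None:
    """Write a landscape grid as TSV with lattice coordinates."""
    with open(path, "w") as fh:
        fh.write("x\ty\tvalue\n")
        for i, gx in enumerate(grid_x):
            for j, gy in enumerate(grid_y):
                fh.write(f"{gx}\t{gy}\t{grid[i][j]}\n")
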