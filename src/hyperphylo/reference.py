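"""Baseline tree-space Metropolis sampler.

A deliberately plain MCMC over trees themselves — nearest-neighbour
interchange (NNI) for topology moves and a multiplicative scaling move for
branch lengths — targeting the same JC69 likelihood and Gamma-Dirichlet
prior as the embedding sampler.  It never touches the embedding machinery,
which makes it a useful independent point of comparison for posterior
summaries at small problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import Alignment, PriorConfig, log_prior
from .evolution import _pruning_loglik
from .trees import PhyloTree

__all__ = ["nni_metropolis"]


@dataclass
class ReferenceTrace:
    generations: list
    trees: list
    log_joints: list


def _nni_neighbors(T: PhyloTree, eidx: int, rng: np.random.Generator) -> PhyloTree:
    """One of the two NNI rearrangements across internal edge ``eidx``."""
    n = T.n_tips
    a, b = T.edges[eidx]
    adj = T.adjacency()
    # subtrees hanging off a (other than b) and off b (other than a)
    a_edges = [e for nbr, e in adj[a] if nbr != b]
    b_edges = [e for nbr, e in adj[b] if nbr != a]
    ea = a_edges[int(rng.integers(2))]
    eb = b_edges[int(rng.integers(2))]
    edges = T.edges.copy()
    # swap the far endpoints of the two chosen edges across the internal edge
    for e, old, new in ((ea, a, b), (eb, b, a)):
        if edges[e, 0] == old:
            edges[e, 0] = new
        else:
            edges[e, 1] = new
    return PhyloTree(list(T.labels), edges, T.lengths.copy())


def nni_metropolis(
    Y: Alignment,
    init_tree: PhyloTree,
    generations: int,
    n_samples: int = 1000,
    prior: PriorConfig | None = None,
    seed: int = 0,
    scale_lambda: float = 1.0,
) -> ReferenceTrace:
    """Vanilla Metropolis sampler in tree space.

    Each generation applies, with equal probability, either an NNI move on
    a uniformly chosen internal edge (symmetric proposal) or a branch
    multiplier ``l -> l * m`` with ``m = exp(scale_lambda * (u - 1/2))`` on
    a uniformly chosen edge (Hastings correction ``+log m``).  Returns
    evenly spaced thinned samples.
    """
    if prior is None:
        prior = PriorConfig()
    rng = np.random.default_rng(seed)
    labels = list(Y.labels)
    order = [init_tree.labels.index(lab) for lab in labels]
    # relabel tips so the tree's tip order matches the alignment
    if order != list(range(len(labels))):
        remap = np.arange(init_tree.n_nodes)
        for new, old in enumerate(order):
            remap[old] = new
        edges = remap[init_tree.edges]
        T = PhyloTree(labels, edges, init_tree.lengths.copy())
    else:
        T = PhyloTree(labels, init_tree.edges.copy(), init_tree.lengths.copy())

    partials, weights = Y.site_patterns()
    n = T.n_tips
    internal_edges = [
        e for e, (a, b) in enumerate(T.edges) if a >= n and b >= n
    ]

    def score(tree):
        lp = log_prior(tree, prior)
        if lp == -np.inf:
            return -np.inf
        return _pruning_loglik(tree, partials, weights) + lp

    lj = score(T)
    n_samples = min(n_samples, generations)
    sample_gens = {
        int(np.floor((k + 1) * generations / n_samples)) - 1 for k in range(n_samples)
    }
    gens, trees, ljs = [], [], []
    for gen in range(generations):
        if internal_edges and rng.random() < 0.5:
            eidx = internal_edges[int(rng.integers(len(internal_edges)))]
            cand = _nni_neighbors(T, eidx, rng)
            log_hastings = 0.0
        else:
            eidx = int(rng.integers(len(T.edges)))
            m = float(np.exp(scale_lambda * (rng.random() - 0.5)))
            lengths = T.lengths.copy()
            lengths[eidx] *= m
            cand = PhyloTree(list(T.labels), T.edges.copy(), lengths)
            log_hastings = np.log(m)
        lj_c = score(cand)
        log_alpha = lj_c - lj + log_hastings
        if log_alpha >= 0 or rng.random() < np.exp(log_alpha):
            T, lj = cand, lj_c
            internal_edges = [
                e for e, (a, b) in enumerate(T.edges) if a >= n and b >= n
            ]
        if gen in sample_gens:
            gens.append(gen + 1)
            trees.append(T)
            ljs.append(lj)
    return ReferenceTrace(gens, trees, ljs)
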