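"""Synthetic phylogenetic fixtures.

Random unrooted binary trees, JC69-evolved alignments on them, exact
additive (tree-metric) distance matrices and bounded perturbations — the
generative counterparts of everything the inference side consumes.  Branch
lengths default to Exponential with mean 0.1 substitutions per site, the
short-tree regime typical of curated benchmark alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import PhyloTree, tree_path_distances, write_newick

__all__ = [
    "SimulationConfig",
    "random_tree",
    "simulate_alignment",
    "additive_distances",
    "perturb_distances",
    "write_fasta",
    "write_tree",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_taxa: int = 8
    branch_length_mean: float = 0.1
    n_sites: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError(f"need n_taxa >= 3, got {self.n_taxa}")
        if self.branch_length_mean <= 0 or self.n_sites < 1:
            raise ValueError("branch_length_mean and n_sites must be positive")


def random_tree(config: SimulationConfig) -> PhyloTree:
    """Uniformly random unrooted binary topology with i.i.d. branch lengths.

    Built by sequential random attachment: starting from the three-taxon
    star, each new tip subdivides a uniformly chosen existing edge.  Every
    unrooted binary topology on n tips arises with equal probability
    1/(2n-5)!!.  Branch lengths are Exponential(mean = branch_length_mean).
    """
    n = config.n_taxa
    rng = np.random.default_rng(config.seed)
    labels = [f"t{i}" for i in range(n)]
    # edges as mutable endpoint lists; node ids: tips 0..n-1, internal n..2n-3
    edges = [[0, n], [1, n], [2, n]]
    next_internal = n + 1
    for tip in range(3, n):
        e = rng.integers(len(edges))
        a, b = edges[e]
        v = next_internal
        next_internal += 1
        edges[e] = [a, v]
        edges.append([b, v])
        edges.append([tip, v])
    lengths = rng.exponential(config.branch_length_mean, size=len(edges))
    return PhyloTree(labels, np.array(edges), lengths)


def simulate_alignment(T: PhyloTree, L: int, seed: int = 0):
    """Evolve an alignment of ``L`` sites on the tree under JC69.

    The root state is uniform over {A,C,G,T} at an arbitrary internal node;
    each edge mutates a site with probability ``(3/4)(1 - e^(-4t/3))`` to a
    uniformly chosen different base.  JC69 is reversible, so the choice of
    root node is immaterial to the joint tip distribution.  Returns an
    :class:`~hyperphylo.evolution.Alignment`.
    """
    from .evolution import Alignment

    if L < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    n_nodes = T.n_nodes
    states = np.empty((n_nodes, L), dtype=np.int8)
    order = T.postorder()
    root = order[-1][0]
    states[root] = rng.integers(4, size=L)
    # walk away from the root (reverse postorder visits parents first)
    for node, parent, eidx in reversed(order[:-1]):
        t = T.lengths[eidx]
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        child = states[parent].copy()
        hit = rng.random(L) < p_change
        # uniform over the three other bases
        child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        states[node] = child
    seqs = ["".join(_BASES[states[i]]) for i in range(T.n_tips)]
    return Alignment(list(T.labels), seqs)


def additive_distances(T: PhyloTree) -> np.ndarray:
    """Exact tree-metric (additive) distance matrix of the tree's tips."""
    return tree_path_distances(T)


def perturb_distances(D: np.ndarray, amplitude: float, seed: int = 0) -> np.ndarray:
    """Add symmetric uniform noise in [-amplitude, amplitude] off-diagonal.

    The result stays symmetric with a zero diagonal and is clamped to be
    non-negative; the sup-norm of the perturbation never exceeds
    ``amplitude``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    D = np.asarray(D, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-amplitude, amplitude, size=D.shape)
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    out = np.maximum(D + noise, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def write_fasta(Y, path) -> None:
    """Write an alignment as plain FASTA."""
    with open(path, "w") as fh:
        for lab, seq in zip(Y.labels, Y.sequences):
            fh.write(f">{lab}\n{seq}\n")


def write_tree(T: PhyloTree, path) -> None:
    """Write a tree as a one-line Newick file."""
    with open(path, "w") as fh:
        fh.write(write_newick(T) + "\n")
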