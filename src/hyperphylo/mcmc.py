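"""Metropolis-coupled MCMC over hyperbolic embedding states.

The sampler's state is the matrix of tangent coordinates X of the embedded
taxa.  Every generation, a joint multivariate Gaussian perturbation of all
n*d coordinates is proposed, the candidate coordinates are projected onto
the hyperboloid, pairwise distances decoded into a neighbour-joining tree,
and the candidate accepted by a tempered Metropolis step on the tree's
unnormalised log posterior.  The proposal is symmetric and no
embedding-to-tree Jacobian term is applied, so the acceptance ratio is the
plain tempered posterior ratio.

Proposal covariance is tuned in two phases: a warm-up that periodically
re-estimates the empirical covariance of the visited states (scaled by the
classic 2.38^2 / dim factor), then robust adaptive Metropolis (RAM)
rank-one updates that steer the realised acceptance rate towards a target
with diminishing step sizes.  Several chains run at tempered posteriors
beta_i = 1 / (1 + lambda (i - 1)) and exchange states by Metropolis swap
moves; only the cold chain is recorded.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.linalg import cholesky

from .embedding import EmbeddingConfig, embed_hydraplus
from .evolution import Alignment, PriorConfig, log_prior, sequence_distances
from .evolution import _pruning_loglik
from .geometry import pairwise_distances
from .trees import PhyloTree, neighbor_joining, tree_length, tree_path_distances

__all__ = [
    "ChainState",
    "MCMCConfig",
    "MCMCTrace",
    "propose",
    "accept_probability",
    "ram_adapt",
    "swap_move",
    "run_mcmc",
]


@dataclass
class MCMCConfig:
    """Run settings; defaults follow common practice for this sampler family.

    ``curvature`` and ``dimension`` select the embedding space (three
    dimensions at curvature -1 by default); ``warmup`` generations of
    empirical-covariance tuning precede RAM adaptation; ``n_chains``
    tempered chains attempt ``swaps_per_interval`` swap moves every
    ``swap_interval`` generations; ``n_samples`` evenly spaced cold-chain
    trees are retained.
    """

    generations: int = 100_000
    warmup: int = 10_000
    n_chains: int = 4
    swap_interval: int = 1_000
    swaps_per_interval: int = 10
    n_samples: int = 10_000
    curvature: float = -1.0
    dimension: int = 3
    seed: int = 0
    start: str = "nj"
    prior: PriorConfig = field(default_factory=PriorConfig)
    temperature_lambda: float = 0.1
    ram_target_rate: float = 0.234
    warmup_update_every: int = 100
    initial_scale: float = 0.01

    def __post_init__(self):
        if self.generations < self.warmup:
            raise ValueError("generations must be >= warmup")
        if self.n_samples > max(self.generations, 1):
            raise ValueError("n_samples must be <= generations")
        if self.curvature > 0:
            raise ValueError("curvature must be <= 0 (0 selects Euclidean mode)")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class ChainState:
    """One tempered chain: coordinates, decoded tree, cached score, proposal scale."""

    X: np.ndarray
    tree: PhyloTree
    log_joint: float
    scale: np.ndarray  # lower-triangular Cholesky factor of the proposal covariance
    beta: float
    accepted: int = 0
    proposed: int = 0

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.proposed if self.proposed else 0.0


@dataclass
class MCMCTrace:
    """Thinned cold-chain samples plus per-chain acceptance statistics."""

    generations: list
    trees: list
    log_joints: list
    acceptance_rates: list
    config: MCMCConfig

    def __len__(self):
        return len(self.trees)

    def tree_lengths(self) -> np.ndarray:
        return np.array([tree_length(T) for T in self.trees])

    def manifest(self) -> dict:
        cfg = asdict(self.config)
        cfg["prior"] = asdict(self.config.prior)
        return {
            "config": cfg,
            "n_samples": len(self.trees),
            "acceptance_rates": self.acceptance_rates,
        }


def propose(state: ChainState, rng: np.random.Generator):
    """Draw a candidate coordinate matrix from N(X, scale @ scale.T).

    One joint Gaussian move over all n*d tangent coordinates; returns the
    candidate and the standardised increment used (needed by RAM).  The
    density is symmetric in (current, candidate).
    """
    n, d = state.X.shape
    z = rng.standard_normal(n * d)
    candidate = state.X + (state.scale @ z).reshape(n, d)
    return candidate, z


def accept_probability(log_joint_current: float, log_joint_candidate: float, beta: float = 1.0) -> float:
    """Tempered Metropolis acceptance probability.

    ``min(1, exp(beta * (candidate - current)))`` — symmetric proposal, no
    Jacobian adjustment for the embedding-to-tree decoding.
    """
    if np.isnan(log_joint_candidate) or log_joint_candidate == -np.inf:
        return 0.0
    diff = beta * (log_joint_candidate - log_joint_current)
    return float(min(1.0, np.exp(min(diff, 0.0))))


def ram_adapt(
    scale: np.ndarray,
    z: np.ndarray,
    accepted_prob: float,
    iteration: int,
    target_rate: float = 0.234,
) -> np.ndarray:
    """Robust adaptive Metropolis rank-one update of the proposal factor.

    Updates ``scale @ scale.T`` by ``eta * (alpha - alpha*)`` in the
    direction of the standardised proposal increment ``z``, with step size
    ``eta = min(1, dim * iteration^(-2/3))`` so adaptation diminishes.  The
    result is the lower-triangular Cholesky factor of the updated
    covariance; on numerical failure the update is skipped.
    """
    dim = scale.shape[0]
    eta = min(1.0, dim * iteration ** (-2.0 / 3.0))
    zz = z @ z
    if zz == 0:
        return scale
    u = scale @ z
    M = scale @ scale.T + eta * (accepted_prob - target_rate) * np.outer(u, u) / zz
    try:
        new = cholesky(M, lower=True)
    except np.linalg.LinAlgError:
        return scale
    if not np.all(np.isfinite(new)):
        return scale
    return new


def swap_move(states: list, rng: np.random.Generator, n_swaps: int = 1) -> int:
    """Attempt state exchanges between adjacent-temperature chains.

    Each attempt picks a random adjacent pair (i, i+1) and swaps their
    (X, tree, log_joint) with probability
    ``min(1, exp((beta_i - beta_j) * (lj_j - lj_i)))``.  Returns the number
    of accepted swaps.  A single chain is a no-op.
    """
    if len(states) < 2:
        return 0
    accepted = 0
    for _ in range(n_swaps):
        i = int(rng.integers(len(states) - 1))
        a, b = states[i], states[i + 1]
        log_ratio = (a.beta - b.beta) * (b.log_joint - a.log_joint)
        if log_ratio >= 0 or rng.random() < np.exp(log_ratio):
            a.X, b.X = b.X, a.X
            a.tree, b.tree = b.tree, a.tree
            a.log_joint, b.log_joint = b.log_joint, a.log_joint
            accepted += 1
    return accepted


def _decode_and_score(X, kappa, partials, weights, labels, prior):
    """Project, decode the NJ tree, and score it: the sampler's inner step."""
    D = pairwise_distances(X, kappa)
    T = neighbor_joining(D, labels, validate=False)
    lp = log_prior(T, prior, X)
    if lp == -np.inf:
        return T, -np.inf
    return T, _pruning_loglik(T, partials, weights) + lp


def run_mcmc(Y: Alignment, config: MCMCConfig, start_tree: PhyloTree | None = None) -> MCMCTrace:
    """Run the full embedding-space sampler on an alignment.

    The initial embedding comes from JC69-corrected sequence distances (or
    the path distances of ``start_tree``), encoded by the hydra+-style
    embedder.  Each generation every chain proposes new coordinates,
    re-decodes the NJ tree and applies the tempered Metropolis step; swap
    moves run between chains on a fixed schedule.  The cold chain is
    thinned to ``n_samples`` evenly spaced samples.  A fixed seed gives a
    bit-identical trace.
    """
    if Y.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if config.start == "given_tree" and start_tree is None:
        raise ValueError("start='given_tree' requires a start tree")
    if start_tree is not None and set(start_tree.labels) != set(Y.labels):
        raise ValueError("start tree and alignment taxon sets differ")

    labels = list(Y.labels)
    if start_tree is not None:
        order = [start_tree.labels.index(lab) for lab in labels]
        D0 = tree_path_distances(start_tree)[np.ix_(order, order)]
    else:
        D0 = sequence_distances(Y, "jc69")
    emb_cfg = EmbeddingConfig(dimension=config.dimension, curvature=config.curvature)
    emb = embed_hydraplus(D0, emb_cfg, labels)
    X0 = emb.tangent
    n, d = X0.shape
    dim = n * d

    partials, weights = Y.site_patterns()
    kappa = config.curvature
    prior = config.prior
    rng = np.random.default_rng(config.seed)

    T0, lj0 = _decode_and_score(X0, kappa, partials, weights, labels, prior)
    if not np.isfinite(lj0):
        raise ValueError("initial embedding decodes to a state of zero posterior density")

    betas = [1.0 / (1.0 + config.temperature_lambda * i) for i in range(config.n_chains)]
    scale0 = config.initial_scale * np.eye(dim)
    states = [
        ChainState(X0.copy(), T0, lj0, scale0.copy(), beta) for beta in betas
    ]

    total = config.generations
    n_samples = min(config.n_samples, max(total - config.warmup, 1))
    post = max(total - config.warmup, 1)
    sample_gens = set(
        config.warmup + int(np.floor((k + 1) * post / n_samples)) - 1
        for k in range(n_samples)
    ) if total > 0 else set()

    gens_out, trees_out, ljs_out = [], [], []
    if total == 0:
        gens_out, trees_out, ljs_out = [0], [T0], [lj0]

    # warm-up bookkeeping: running history of cold-dimension states per chain
    histories = [[] for _ in states]

    for gen in range(total):
        in_warmup = gen < config.warmup
        for ci, st in enumerate(states):
            candidate, z = propose(st, rng)
            T_c, lj_c = _decode_and_score(candidate, kappa, partials, weights, labels, prior)
            alpha = accept_probability(st.log_joint, lj_c, st.beta)
            st.proposed += 1
            if alpha > 0 and (alpha >= 1.0 or rng.random() < alpha):
                st.X, st.tree, st.log_joint = candidate, T_c, lj_c
                st.accepted += 1
            if in_warmup:
                histories[ci].append(st.X.ravel().copy())
                if (gen + 1) % config.warmup_update_every == 0 and len(histories[ci]) > 2 * dim:
                    cov = np.cov(np.array(histories[ci][-5000:]), rowvar=False)
                    cov = 2.38**2 / dim * cov + 1e-12 * np.eye(dim)
                    try:
                        st.scale = cholesky(cov, lower=True)
                    except np.linalg.LinAlgError:
                        pass
            else:
                st.scale = ram_adapt(
                    st.scale, z, alpha, gen - config.warmup + 1, config.ram_target_rate
                )
        if config.n_chains > 1 and (gen + 1) % config.swap_interval == 0:
            swap_move(states, rng, config.swaps_per_interval)
        if gen in sample_gens:
            cold = states[0]
            gens_out.append(gen + 1)
            trees_out.append(cold.tree)
            ljs_out.append(cold.log_joint)

    return MCMCTrace(
        generations=gens_out,
        trees=trees_out,
        log_joints=ljs_out,
        acceptance_rates=[st.acceptance_rate for st in states],
        config=config,
    )
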