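"""Sequence data and the probabilistic model.

The model is deliberately minimal: a JC69 substitution process (uniform base
frequencies, a single exchange rate, so branch lengths are in expected
substitutions per site) scored by Felsenstein pruning, combined with a
uniform prior over unrooted topologies and a Gamma-Dirichlet prior on branch
lengths — a Gamma(alpha, beta) on the total tree length split into branch
proportions by a symmetric Dirichlet.  The product gives the unnormalised
log posterior that the embedding sampler targets; the marginal likelihood of
the data is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.special import gammaln

from .trees import PhyloTree

__all__ = [
    "Alignment",
    "PriorConfig",
    "read_fasta",
    "read_nexus_alignment",
    "read_alignment",
    "sequence_distances",
    "jc69_transition_probability",
    "log_likelihood",
    "log_prior",
    "log_joint",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class Alignment:
    """A multiple sequence alignment of nucleotides.

    Non-ACGT symbols (gaps, ambiguity codes) are retained but treated as
    fully missing data by the likelihood and excluded from pairwise distance
    computation.
    """

    labels: list
    sequences: list
    _partials: np.ndarray = field(default=None, repr=False, compare=False)
    _weights: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.labels) != len(self.sequences):
            raise ValueError("label and sequence counts differ")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("taxon labels must be unique")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.n_sites < 1:
            raise ValueError("alignment has no sites")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def site_patterns(self):
        """Compress columns into unique site patterns.

        Returns ``(partials, weights)`` where ``partials`` has shape
        (n_taxa, 4, P) — the tip conditional likelihoods, all-ones for
        missing states — and ``weights`` counts how many alignment columns
        each pattern represents.  Cached after the first call.
        """
        if self._partials is not None:
            return self._partials, self._weights
        n, L = self.n_taxa, self.n_sites
        codes = np.full((n, L), 4, dtype=np.int8)
        for i, seq in enumerate(self.sequences):
            for j, c in enumerate(seq):
                codes[i, j] = _BASE_INDEX.get(c, 4)
        _, first, counts = np.unique(
            codes, axis=1, return_index=True, return_counts=True
        )
        pat = codes[:, first]
        lookup = np.vstack([np.eye(4), np.ones(4)])  # code -> partial row
        partials = np.ascontiguousarray(np.transpose(lookup[pat], (0, 2, 1)))
        object.__setattr__(self, "_partials", partials)
        object.__setattr__(self, "_weights", counts.astype(float))
        return self._partials, self._weights


@dataclass
class PriorConfig:
    """Prior on trees (or, alternatively, on embedding locations).

    ``gamma_dirichlet`` (default): Gamma(shape, rate) on the total tree
    length, symmetric Dirichlet(dirichlet_alpha) on branch-length
    proportions, uniform over topologies.  ``embedding_normal``: independent
    standard Normal on every stored embedding coordinate, no tree term.
    """

    gamma_shape: float = 1.0
    gamma_rate: float = 0.1
    dirichlet_alpha: float = 1.0
    mode: str = "gamma_dirichlet"

    def __post_init__(self):
        if min(self.gamma_shape, self.gamma_rate, self.dirichlet_alpha) <= 0:
            raise ValueError("prior parameters must be positive")
        if self.mode not in ("gamma_dirichlet", "embedding_normal"):
            raise ValueError(f"unknown prior mode {self.mode!r}")


def read_fasta(path) -> Alignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def read_nexus_alignment(path) -> Alignment:
    mat = dendropy.DnaCharacterMatrix.get(path=str(path), schema="nexus")
    labels = [t.label for t in mat.taxon_namespace]
    seqs = [str(mat[t]).replace(" ", "") for t in mat.taxon_namespace]
    return Alignment(labels, seqs)


def read_alignment(path) -> Alignment:
    """Read FASTA or NEXUS, sniffing the format from the first line."""
    with open(path) as fh:
        head = fh.readline()
    if head.lstrip().startswith(">"):
        return read_fasta(path)
    return read_nexus_alignment(path)


def sequence_distances(
    Y: Alignment, correction: str = "jc69", saturation_cap: float = 10.0
) -> np.ndarray:
    """Pairwise evolutionary distances between aligned sequences.

    ``raw_hamming``: proportion of differing sites among sites where both
    sequences are unambiguous ACGT.  ``jc69``: the distance-correction
    ``-(3/4) ln(1 - 4p/3)`` of that proportion, the expected number of
    substitutions per site under JC69; saturated pairs (p >= 3/4) are mapped
    to ``saturation_cap`` so arbitrary alignments remain embeddable.
    """
    if correction not in ("raw_hamming", "jc69"):
        raise ValueError(f"unknown correction {correction!r}")
    n = Y.n_taxa
    if n < 3:
        raise ValueError(f"need n >= 3 sequences, got {n}")
    codes = np.full((n, Y.n_sites), 4, dtype=np.int8)
    for i, seq in enumerate(Y.sequences):
        codes[i] = [_BASE_INDEX.get(c, 4) for c in seq]
    good = codes != 4
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = good[i] & good[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {Y.labels[i]!r} and {Y.labels[j]!r}"
                )
            p = float(np.sum(codes[i, both] != codes[j, both])) / m
            if correction == "raw_hamming":
                d = p
            elif p >= 0.75:
                d = saturation_cap
            else:
                d = -0.75 * np.log1p(-4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return D


def jc69_transition_probability(t: float):
    """JC69 transition probabilities over a branch of length ``t``.

    Returns ``(p_same, p_diff)`` with ``p_same = 1/4 + (3/4) e^(-4t/3)`` and
    ``p_diff = 1/4 - (1/4) e^(-4t/3)``; ``p_same + 3 p_diff = 1``.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    e = np.exp(-4.0 * t / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def _pruning_loglik(
    T: PhyloTree, tip_partials: np.ndarray, weights: np.ndarray, root: int | None = None
) -> float:
    """Felsenstein pruning over compressed site patterns.

    Under JC69 the per-branch message has the closed form
    ``p_diff * colsum + (p_same - p_diff) * partial`` which avoids explicit
    4x4 matrix products.
    """
    n_nodes = T.n_nodes
    P = tip_partials.shape[2]
    partials = np.ones((n_nodes, 4, P))
    partials[: T.n_tips] = tip_partials
    e = np.exp(-4.0 * T.lengths / 3.0)
    p_same = 0.25 + 0.75 * e
    p_diff = 0.25 - 0.25 * e
    scale = np.zeros(P)
    order = T.postorder(root)
    for node, parent, eidx in order:
        if parent < 0:
            break
        part = partials[node]
        msg = p_diff[eidx] * part.sum(axis=0) + (p_same[eidx] - p_diff[eidx]) * part
        partials[parent] *= msg
        if node >= T.n_tips:
            # rescale to dodge underflow on deep trees
            m = partials[parent].max(axis=0)
            m[m == 0] = 1.0
            partials[parent] /= m
            scale += np.log(m)
    root = order[-1][0]
    site = 0.25 * partials[root].sum(axis=0)
    return float(weights @ (np.log(site) + scale))


def log_likelihood(T: PhyloTree, Y: Alignment) -> float:
    """JC69 log-likelihood of the alignment on the tree by pruning.

    Base frequencies are uniform (1/4 each); gaps and ambiguity codes enter
    as missing data (all-ones tip partials).  The value is invariant to the
    internal node chosen as traversal root.
    """
    if set(T.labels) != set(Y.labels):
        raise ValueError("tree and alignment taxon sets differ")
    partials, weights = Y.site_patterns()
    if T.labels != Y.labels:
        order = [Y.labels.index(lab) for lab in T.labels]
        partials = partials[order]
    return _pruning_loglik(T, partials, weights)


def log_prior(
    T: PhyloTree, prior: PriorConfig | None = None, X: np.ndarray | None = None
) -> float:
    """Log prior density of a tree (or of embedding coordinates).

    In ``gamma_dirichlet`` mode the density is evaluated on the vector of
    branch lengths: with total length TL and proportions p_e = l_e / TL,

        log Gamma(TL; shape, rate) + log Dir(p; alpha) - (K-1) log TL

    where the last term is the change of variables from (TL, p) to branch
    lengths — without it Metropolis-Hastings ratios on branch lengths would
    be computed under the wrong measure.  The uniform-topology constant is
    dropped (constant across states).  In ``embedding_normal`` mode the
    tree plays no role and the density is a standard Normal on every entry
    of ``X``.
    """
    if prior is None:
        prior = PriorConfig()
    if prior.mode == "embedding_normal":
        if X is None:
            raise ValueError("embedding_normal prior needs the embedding coordinates X")
        X = np.asarray(X, dtype=float)
        return float(-0.5 * np.sum(X * X) - 0.5 * X.size * np.log(2 * np.pi))

    lengths = T.lengths
    if np.any(lengths < 0):
        raise ValueError("branch lengths must be non-negative")
    K = lengths.size
    TL = float(lengths.sum())
    if TL <= 0:
        return -np.inf
    a, b, da = prior.gamma_shape, prior.gamma_rate, prior.dirichlet_alpha
    log_gamma = a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(TL) - b * TL
    p = lengths / TL
    log_dir = gammaln(K * da) - K * gammaln(da)
    if da != 1.0:
        if np.any(p == 0):
            return -np.inf
        log_dir += (da - 1.0) * float(np.sum(np.log(p)))
    return float(log_gamma + log_dir - (K - 1) * np.log(TL))


def log_joint(
    T: PhyloTree,
    Y: Alignment,
    prior: PriorConfig | None = None,
    X: np.ndarray | None = None,
) -> float:
    """Unnormalised log posterior: log p(Y|T) + log p(T)."""
    lp = log_prior(T, prior, X)
    if lp == -np.inf:
        return -np.inf
    return log_likelihood(T, Y) + lp
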