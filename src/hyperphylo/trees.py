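"""Unrooted phylogenetic trees and neighbour-joining decoding.

A :class:`PhyloTree` is an unrooted binary tree over labelled tips with a
branch length per edge.  Tips are nodes ``0..n-1`` (in taxon-label order),
internal nodes are ``n..2n-3``; an n-tip tree has exactly ``2n-3`` edges and
``n-2`` internal nodes of degree three.

:func:`neighbor_joining` is the decoder at the heart of the embedding
sampler: it turns any pairwise distance matrix into a tree (topology and
branch lengths at once) and is consistent — an additive matrix yields the
unique generating tree exactly.  Ties in the Q criterion are broken by the
lexicographically smallest index pair so decoding is deterministic, and
negative branch-length estimates are clamped to zero so the decoded tree is
always inside the support of the branch-length prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "PhyloTree",
    "neighbor_joining",
    "tree_path_distances",
    "tree_splits",
    "rf_distance",
    "tree_length",
    "read_newick",
    "write_newick",
    "write_nexus_trace",
]


@dataclass
class PhyloTree:
    """Unrooted binary tree with labelled tips and branch lengths.

    Attributes
    ----------
    labels : list of str
        Taxon labels; tip node ``i`` carries ``labels[i]``.
    edges : ndarray of int, shape (2n-3, 2)
        Node-id pairs; node ids ``0..n-1`` are tips, the rest internal.
    lengths : ndarray of float, shape (2n-3,)
        Non-negative branch length per edge.
    """

    labels: list
    edges: np.ndarray
    lengths: np.ndarray
    _splits: frozenset = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.intp)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("taxon labels must be unique")
        if n < 3:
            raise ValueError(f"need at least 3 tips, got {n}")
        if self.edges.shape != (2 * n - 3, 2) or self.lengths.shape != (2 * n - 3,):
            raise ValueError(
                f"{n} tips require 2n-3 = {2 * n - 3} edges, got "
                f"{self.edges.shape[0]} edges and {self.lengths.shape[0]} lengths"
            )
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 2

    def adjacency(self):
        """Neighbour lists: node -> list of (neighbour, edge index)."""
        adj = [[] for _ in range(self.n_nodes)]
        for e, (a, b) in enumerate(self.edges):
            adj[a].append((b, e))
            adj[b].append((a, e))
        return adj

    def postorder(self, root: int | None = None):
        """Postorder traversal rooted at ``root`` (default: last internal node).

        Yields ``(node, parent, edge_index)`` with the root last
        (``parent = -1``, ``edge_index = -1``).  The rooting is a traversal
        device only; the tree remains unrooted.
        """
        if root is None:
            root = self.n_nodes - 1
        adj = self.adjacency()
        order = []
        stack = [(root, -1, -1)]
        while stack:
            node, parent, eidx = stack.pop()
            order.append((node, parent, eidx))
            for nbr, e in adj[node]:
                if nbr != parent:
                    stack.append((nbr, node, e))
        return order[::-1]


_TRIU_CACHE: dict = {}


def _triu(n: int):
    if n not in _TRIU_CACHE:
        _TRIU_CACHE[n] = np.triu_indices(n, k=1)
    return _TRIU_CACHE[n]


def neighbor_joining(D: np.ndarray, labels: list, validate: bool = True) -> PhyloTree:
    """Decode an unrooted binary tree from a distance matrix by NJ.

    Standard neighbour joining: repeatedly merge the pair minimising the
    Q criterion ``Q_ij = (N-2) D_ij - r_i - r_j``, assign branch lengths by
    the usual formulas, and reduce the matrix, until three clusters remain
    and are joined to a final internal node.  Consistent on additive inputs.
    ``validate=False`` skips the input checks (for callers that construct
    the matrix themselves in a tight loop).
    """
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    if n < 3:
        raise ValueError(f"neighbour joining needs n >= 3 taxa, got {n}")
    if validate:
        if D.ndim != 2 or D.shape[1] != n or len(labels) != n:
            raise ValueError(
                f"distance matrix shape {D.shape} does not match {len(labels)} labels"
            )
        if np.any(np.isnan(D)):
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")

    node_ids = list(range(n))  # active cluster -> tree node id
    next_node = n
    edges: list[tuple[int, int]] = []
    lengths: list[float] = []
    active = list(range(n))  # indices into the shrinking matrix rows

    # work on a copy that we shrink by overwriting row/col of j with the
    # merged cluster and dropping the row/col of i
    M = D
    ids = node_ids[:]
    while len(ids) > 3:
        N = len(ids)
        r = M.sum(axis=1)
        Q = (N - 2) * M - r[:, None] - r[None, :]
        # only i<j; row-major argmin over the upper triangle gives the
        # lexicographically smallest pair among exact ties
        iu = _triu(N)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])

        dij = M[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_node
        next_node += 1
        edges.append((ids[i], u))
        lengths.append(li)
        edges.append((ids[j], u))
        lengths.append(lj)

        # distances from the new cluster to the remainder
        du = 0.5 * (M[i] + M[j] - dij)
        keep = [t for t in range(N) if t not in (i, j)]
        M2 = np.empty((N - 1, N - 1))
        M2[:-1, :-1] = M[np.ix_(keep, keep)]
        M2[-1, :-1] = du[keep]
        M2[:-1, -1] = du[keep]
        M2[-1, -1] = 0.0
        M = M2
        ids = [ids[t] for t in keep] + [u]

    # terminal three-way join: the centre node connects the survivors with
    # the three-point closed-form lengths
    a, b, c = 0, 1, 2
    centre = next_node
    la = 0.5 * (M[a, b] + M[a, c] - M[b, c])
    lb = 0.5 * (M[a, b] + M[b, c] - M[a, c])
    lc = 0.5 * (M[a, c] + M[b, c] - M[a, b])
    for t, lt in zip((a, b, c), (la, lb, lc)):
        edges.append((ids[t], centre))
        lengths.append(max(lt, 0.0))

    return PhyloTree(list(labels), np.array(edges), np.array(lengths))


def tree_path_distances(T: PhyloTree) -> np.ndarray:
    """Tip-to-tip path-length matrix (sums of branch lengths)."""
    n_nodes = T.n_nodes
    rows = np.concatenate([T.edges[:, 0], T.edges[:, 1]])
    cols = np.concatenate([T.edges[:, 1], T.edges[:, 0]])
    w = np.concatenate([T.lengths, T.lengths])
    graph = csr_matrix((w, (rows, cols)), shape=(n_nodes, n_nodes))
    # unweighted structure must survive zero-length branches, so shift all
    # weights by 1 and subtract the hop count afterwards
    hop = csr_matrix((np.ones_like(w), (rows, cols)), shape=(n_nodes, n_nodes))
    full = shortest_path(graph + hop, method="D", indices=range(T.n_tips))
    hops = shortest_path(hop, method="D", indices=range(T.n_tips), unweighted=True)
    D = full[:, : T.n_tips] - hops[:, : T.n_tips]
    D = 0.5 * (D + D.T)  # per-source runs agree only to rounding
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def tree_splits(T: PhyloTree) -> frozenset:
    """Non-trivial splits (bipartitions) of the taxon set, canonicalised.

    Each internal edge induces a bipartition; it is stored as the frozenset
    of labels on the side *not* containing the first taxon label, so equal
    splits always compare equal.  An n-tip tree has n-3 of them.
    """
    if T._splits is not None:
        return T._splits
    n = T.n_tips
    adj = T.adjacency()
    splits = set()
    for e, (a, b) in enumerate(T.edges):
        if a < n or b < n:
            continue  # pendant edge -> trivial split
        # tips on the b side of edge (a, b)
        side = set()
        stack = [(b, a)]
        while stack:
            node, parent = stack.pop()
            if node < n:
                side.add(node)
            for nbr, _ in adj[node]:
                if nbr != parent:
                    stack.append((nbr, node))
        if 0 in side:
            side = set(range(n)) - side
        splits.add(frozenset(T.labels[i] for i in side))
    result = frozenset(splits)
    object.__setattr__(T, "_splits", result)
    return result


def rf_distance(T1: PhyloTree, T2: PhyloTree) -> int:
    """Robinson-Foulds distance: size of the symmetric split-set difference."""
    if set(T1.labels) != set(T2.labels):
        raise ValueError("trees are over different taxon sets")
    return len(tree_splits(T1) ^ tree_splits(T2))


def tree_length(T: PhyloTree) -> float:
    """Total tree length, the sum of all branch lengths."""
    return float(T.lengths.sum())


# ---------------------------------------------------------------------------
# Newick / NEXUS interchange (dendropy-backed parsing)


def _to_dendropy(T: PhyloTree, taxon_namespace=None) -> dendropy.Tree:
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(T.labels)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes = {}
    order = T.postorder()
    root_id = order[-1][0]
    for node, parent, eidx in order:
        dnode = dendropy.Node()
        if node < T.n_tips:
            dnode.taxon = taxon_namespace.get_taxon(T.labels[node])
        if eidx >= 0:
            dnode.edge.length = float(T.lengths[eidx])
        nodes[node] = dnode
    for node, parent, _ in order:
        if parent >= 0:
            nodes[parent].add_child(nodes[node])
    tree.seed_node = nodes[root_id]
    tree.is_rooted = False
    return tree


def _from_dendropy(tree: dendropy.Tree) -> PhyloTree:
    tree = tree.clone(depth=1)
    tree.is_rooted = False
    # collapse a degree-2 root left by rooted newick strings
    if len(tree.seed_node.child_nodes()) == 2:
        tree.collapse_basal_bifurcation()
    tips = [leaf for leaf in tree.leaf_node_iter()]
    labels = sorted(t.taxon.label for t in tips)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    ids = {}
    next_internal = n
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ids[node] = index[node.taxon.label]
        else:
            ids[node] = next_internal
            next_internal += 1
    edges, lengths = [], []
    for node in tree.postorder_node_iter():
        if node.parent_node is not None:
            edges.append((ids[node], ids[node.parent_node]))
            lengths.append(node.edge.length if node.edge.length is not None else 0.0)
    return PhyloTree(labels, np.array(edges), np.array(lengths))


def write_newick(T: PhyloTree) -> str:
    """Serialise to a Newick string (unrooted, branch lengths, no supports)."""
    dt = _to_dendropy(T)
    return dt.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(source: str) -> PhyloTree:
    """Parse a Newick string or file path into a :class:`PhyloTree`."""
    if "(" in source:
        tree = dendropy.Tree.get(data=source, schema="newick")
    else:
        tree = dendropy.Tree.get(path=source, schema="newick")
    return _from_dendropy(tree)


def write_nexus_trace(trees, generations, path_or_buf) -> None:
    """Write a NEXUS tree trace (translate block + one numbered tree per sample).

    Follows the MrBayes ``.t`` dialect: a taxa translate table then lines
    ``tree gen.<g> = [&U] (...)`` so standard posterior-summary tools can
    consume the trace.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree trace")
    labels = trees[0].labels
    lines = ["#NEXUS", "", "begin trees;", "\ttranslate"]
    for i, lab in enumerate(labels):
        sep = "," if i < len(labels) - 1 else ";"
        lines.append(f"\t\t{i + 1} {lab}{sep}")
    number = {lab: str(i + 1) for i, lab in enumerate(labels)}
    for gen, T in zip(generations, trees):
        dt = _to_dendropy(T)
        for leaf in dt.leaf_node_iter():
            leaf.taxon.label = number[leaf.taxon.label]
        newick = dt.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        lines.append(f"tree gen.{gen} = [&U] {newick}")
    lines.append("end;")
    text = "\n".join(lines) + "\n"
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
        with open(path_or_buf, "w") as fh:
            fh.write(text)
    else:
        path_or_buf.write(text)
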