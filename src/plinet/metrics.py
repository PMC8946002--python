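"""Weighted graph-theory and minimum-spanning-tree network measures.

Given a symmetric nonnegative connectivity matrix W (PLI values, zero
diagonal), this module computes the nine per-subject summary scalars:

- ``pli_mean`` — mean upper-triangle connectivity;
- ``gamma`` — mean weighted clustering coefficient normalized by its mean
  over weight-shuffled surrogate networks;
- ``lambda_`` — characteristic path length (edge distance 1/w) normalized
  the same way;
- ``kappa_w`` — weighted degree divergence, the second moment of the node
  strength distribution over its first moment;
- ``modularity`` — weighted Newman modularity Q of the best partition
  found by seeded Louvain optimization;
- the four MST measures (maximum betweenness centrality, diameter,
  eccentricity, leaf fraction) of the maximum-synchronization spanning
  tree, all hop-count based and normalized into [0, 1].

The clustering coefficient is the weighted triple-product ratio
(products of edge weights in numerator and denominator), the variant used
by the Brainwave lineage of EEG network analysis; an Onnela-style
geometric-mean variant is available through ``weighted_clustering``'s
``variant`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .types import NetworkMeasures


def _check_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"W must be square, got shape {W.shape}")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if W.min() < 0:
        raise ValueError("W must be nonnegative")
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W


# ---------------------------------------------------------------------------
# Weighted measures
# ---------------------------------------------------------------------------

def weighted_clustering(W: np.ndarray, variant: str = "triple") -> float:
    """Mean weighted clustering coefficient.

    ``triple`` (default): per node i,
    C_i = sum_{j != k} w_ij w_jk w_ki / sum_{j != k} w_ij w_ki, i.e. the
    weight of closed triples over the weight of all triples centred on i;
    nodes with zero denominator contribute 0. Reduces to the binary
    clustering coefficient on 0/1 graphs. ``onnela``: geometric-mean
    triangle intensity over degree pairs, on the weights as given.
    """
    W = _check_matrix(W)
    n = W.shape[0]
    if variant == "triple":
        num = np.diag(W @ W @ W)                      # 2 * closed-triple weight
        s = W.sum(axis=1)
        den = s**2 - (W**2).sum(axis=1)               # 2 * all-triple weight
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(den > 0, num / den, 0.0)
        return float(C.mean())
    if variant == "onnela":
        Wc = np.cbrt(W)
        num = np.diag(Wc @ Wc @ Wc)
        k = (W > 0).sum(axis=1)
        den = k * (k - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.where(den > 0, num / den, 0.0)
        return float(C.mean())
    raise ValueError(f"unknown clustering variant {variant!r}")


def char_path_length(W: np.ndarray, warn_disconnected: bool = True) -> float:
    """Characteristic path length with edge distance 1/w.

    Shortest-path distances over d_ij = 1/w_ij (infinite where w_ij = 0);
    the mean is taken over all ordered pairs with finite distance.
    Disconnected pairs are excluded (with a warning) — PLI matrices are
    almost surely complete, so this is a degenerate-input guard.
    """
    W = _check_matrix(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        D = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(D, 0.0)
    SP = shortest_path(D, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(SP) & off
    if warn_disconnected and finite.sum() < off.sum():
        import logging
        logging.getLogger(__name__).warning(
            "disconnected pairs excluded from characteristic path length"
        )
    if not finite.any():
        raise ValueError("graph has no connected pair")
    return float(SP[finite].mean())


def shuffle_surrogate(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of the upper-triangle weights, symmetry restored."""
    W = _check_matrix(W)
    n = W.shape[0]
    iu = np.triu_indices(n, 1)
    vals = rng.permutation(W[iu])
    S = np.zeros_like(W)
    S[iu] = vals
    return S + S.T


def normalize_measures(W: np.ndarray, n_surrogates: int = 50, seed: int = 0,
                       ) -> tuple[float, float]:
    """(gamma, lambda): clustering and path length over surrogate means.

    Surrogates preserve the weight distribution but destroy topology by
    uniformly permuting the upper-triangle weights. Seed-deterministic.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    c_obs = weighted_clustering(W)
    l_obs = char_path_length(W)
    cs, ls = [], []
    for _ in range(n_surrogates):
        S = shuffle_surrogate(W, rng)
        cs.append(weighted_clustering(S))
        ls.append(char_path_length(S, warn_disconnected=False))
    c_ref, l_ref = float(np.mean(cs)), float(np.mean(ls))
    if c_ref == 0 or l_ref == 0:
        raise ValueError("surrogate mean of zero: normalization undefined")
    return c_obs / c_ref, l_obs / l_ref


def kappa_w(W: np.ndarray) -> float:
    """Weighted degree divergence: sum(s_i^2) / sum(s_i) of node strengths."""
    W = _check_matrix(W)
    s = W.sum(axis=1)
    tot = s.sum()
    if tot == 0:
        raise ValueError("all-zero matrix: degree divergence undefined")
    return float((s**2).sum() / tot)


def modularity(W: np.ndarray, seed: int = 0, return_partition: bool = False):
    """Weighted Newman modularity Q of the best Louvain partition.

    Q = sum_c [ e_c / m - (d_c / 2m)^2 ] with weighted within-community
    edge mass e_c, community strength d_c and total edge mass m. The
    Louvain sweep order is seed-deterministic.
    """
    W = _check_matrix(W)
    if W.sum() == 0:
        raise ValueError("all-zero matrix: modularity undefined")
    G = nx.from_numpy_array(W)
    parts = nx.community.louvain_communities(G, weight="weight", seed=seed)
    Q = nx.community.modularity(G, parts, weight="weight")
    if return_partition:
        return float(Q), [set(p) for p in parts]
    return float(Q)


# ---------------------------------------------------------------------------
# Minimum spanning tree (maximum synchronization)
# ---------------------------------------------------------------------------

@dataclass
class SpanningTree:
    """A spanning tree over the channel set."""

    nodes: list[str]
    edges: list[tuple[int, int, float]]  # (i, j, weight), i < j

    def __post_init__(self) -> None:
        N = len(self.nodes)
        if len(self.edges) != N - 1:
            raise ValueError(f"spanning tree over {N} nodes needs {N - 1} edges")
        G = nx.Graph()
        G.add_nodes_from(range(N))
        G.add_edges_from((i, j) for i, j, _ in self.edges)
        if not nx.is_connected(G) or len(G.edges) != N - 1:
            raise ValueError("edges do not form a spanning tree")

    @property
    def N(self) -> int:
        return len(self.nodes)

    @property
    def M(self) -> int:
        return len(self.edges)

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.N))
        G.add_weighted_edges_from(self.edges)
        return G


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(W: np.ndarray, labels: list[str] | None = None) -> SpanningTree:
    """Maximum-weight spanning tree by Kruskal on descending weight.

    Maximizing total synchronization weight is equivalent to the minimum
    spanning tree on distance 1 - w. Ties are broken by lexicographic
    node-pair order, making the tree deterministic under weight ties.
    The result is invariant to scaling all weights by a positive constant.
    """
    W = _check_matrix(W)
    n = W.shape[0]
    if labels is None:
        labels = [str(k) for k in range(n)]
    candidates = sorted(
        ((i, j, W[i, j]) for i in range(n) for j in range(i + 1, n) if W[i, j] > 0),
        key=lambda e: (-e[2], e[0], e[1]),
    )
    uf = _UnionFind(n)
    edges = []
    for i, j, w in candidates:
        if uf.union(i, j):
            edges.append((i, j, float(w)))
            if len(edges) == n - 1:
                break
    if len(edges) != n - 1:
        comp = {uf.find(k) for k in range(n)}
        raise ValueError(
            f"graph disconnected under positive weights ({len(comp)} components)"
        )
    return SpanningTree(list(labels), edges)


def mst_metrics(tree: SpanningTree) -> tuple[float, float, float, float]:
    """(bc_max, diameter, eccentricity, leaf) of a spanning tree.

    All four are topology-only (hop-count) measures normalized into
    [0, 1]: leaf fraction L/M where L counts degree-1 nodes and M = N - 1;
    diameter and per-node eccentricity in hops divided by M; maximum
    betweenness centrality divided by (N - 1)(N - 2)/2, so the center of a
    star attains exactly 1.
    """
    N, M = tree.N, tree.M
    if N < 3:
        raise ValueError("MST metrics need at least 3 nodes")
    G = tree.graph()
    degs = dict(G.degree())
    leaf = sum(1 for d in degs.values() if d == 1) / M

    hop = dict(nx.all_pairs_shortest_path_length(G))
    ecc_per_node = [max(hop[u].values()) for u in G.nodes]
    diameter = max(ecc_per_node) / M
    eccentricity = float(np.mean(ecc_per_node)) / M

    bc = nx.betweenness_centrality(G, normalized=True, weight=None)
    bc_max = max(bc.values())
    return float(bc_max), float(diameter), float(eccentricity), float(leaf)


# ---------------------------------------------------------------------------
# Full measure set
# ---------------------------------------------------------------------------

def compute_measures(W: np.ndarray, n_surrogates: int = 50, seed: int = 0,
                     labels: list[str] | None = None) -> NetworkMeasures:
    """All nine network measures of one connectivity matrix."""
    from .connectivity import mean_pli

    W = _check_matrix(W)
    gamma, lambda_ = normalize_measures(W, n_surrogates=n_surrogates, seed=seed)
    tree = build_mst(W, labels)
    bc_max, diameter, eccentricity, leaf = mst_metrics(tree)
    return NetworkMeasures(
        pli_mean=mean_pli(W),
        gamma=gamma,
        lambda_=lambda_,
        kappa_w=kappa_w(W),
        modularity=modularity(W, seed=seed),
        mst_bc_max=bc_max,
        mst_diameter=diameter,
        mst_eccentricity=eccentricity,
        mst_leaf=leaf,
    )
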